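"""Two-stream CNN classifiers for SE/TE signature pairs.

Three backbone families share the two-stream arrangement — one feature
extractor per signature type, features concatenated into a softmax head:

* ``escape``: classical conv → pool → conv → pool → dense stack with
  dropout after the dense layers.  At full width (width_mult = 1) the
  per-stream dense layer dominates and the parameter count lands in the
  ~90-million range.
* ``residual``: a convolutional stem followed by identity-skip residual
  blocks and global average pooling (tens of millions of parameters at
  full width).
* ``mobile``: inverted-bottleneck blocks (pointwise expand → depthwise →
  pointwise project) with skip connections wherever shapes allow — the
  lightest family.

The training protocol is SGD with learning rate 1e-3, learning-rate decay
1e-6 and momentum 1e-9 (reproduced as stated — effectively zero momentum),
batch size 128, early stopping on validation loss with patience 15 epochs
for ``escape`` and 40 for the other backbones, restoring the
best-validation weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cuffsim import nn


class ModelError(ValueError):
    """Invalid model or training configuration."""


BACKBONES = ("escape", "residual", "mobile")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    backbone: str = "escape"
    n_classes: int = 3
    width_mult: float = 1.0
    dropout: float = 0.5
    input_shape: tuple[int, int] = (56, 100)

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ModelError(f"unknown backbone {self.backbone!r}")
        if self.n_classes < 2:
            raise ModelError("need at least two classes")

    @classmethod
    def desk(cls, backbone: str = "escape", n_classes: int = 3) -> "ModelSpec":
        """Desk profile: ~1/16 width, CPU-trainable in minutes."""
        return cls(backbone=backbone, n_classes=n_classes, width_mult=1.0 / 16.0)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 1e-6
    weight_decay: float = 0.0
    momentum: float = 1e-9
    patience: int = 15
    max_epochs: int = 50
    batch_size: int = 128
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ModelError("patience must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ModelError("val_fraction must be in (0, 1)")

    @classmethod
    def for_backbone(cls, backbone: str, **overrides) -> "TrainConfig":
        patience = 15 if backbone == "escape" else 40
        overrides.setdefault("patience", patience)
        return cls(**overrides)


def _ch(base: int, width_mult: float) -> int:
    return max(1, int(round(base * width_mult)))


def _escape_stream(spec: ModelSpec, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    h, w = spec.input_shape
    c1, c2 = _ch(64, spec.width_mult), _ch(128, spec.width_mult)
    dense = _ch(1024, spec.width_mult)
    h2, w2 = h // 2 // 2, w // 2 // 2
    stream = nn.Sequential(
        [
            nn.Conv2D(1, c1, (5, 5), rng, input_grad=False),
            nn.ReLU(),
            nn.MaxPool2D((2, 2)),
            nn.Conv2D(c1, c2, (3, 3), rng),
            nn.ReLU(),
            nn.MaxPool2D((2, 2)),
            nn.Flatten(),
            nn.Dense(h2 * w2 * c2, dense, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout, rng),
        ]
    )
    return stream, dense


def _residual_stream(spec: ModelSpec, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    stem = _ch(64, spec.width_mult)
    body_ch = _ch(256, spec.width_mult)
    n_blocks = 8 if spec.width_mult >= 0.5 else 2
    layers: list[nn.Layer] = [
        nn.Conv2D(1, stem, (5, 5), rng, input_grad=False),
        nn.ReLU(),
        nn.MaxPool2D((2, 2)),
        nn.Conv2D(stem, body_ch, (1, 1), rng),
        nn.ReLU(),
        nn.MaxPool2D((2, 2)),
    ]
    for _ in range(n_blocks):
        layers.append(
            nn.Residual(
                nn.Sequential(
                    [
                        nn.Conv2D(body_ch, body_ch, (3, 3), rng),
                        nn.ReLU(),
                        nn.Conv2D(body_ch, body_ch, (3, 3), rng),
                    ]
                )
            )
        )
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers), body_ch


def _mobile_stream(spec: ModelSpec, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    stem = _ch(32, spec.width_mult)
    plan = [(stem, _ch(64, spec.width_mult)), (_ch(64, spec.width_mult), _ch(96, spec.width_mult))]
    layers: list[nn.Layer] = [
        nn.Conv2D(1, stem, (3, 3), rng, input_grad=False),
        nn.ReLU(),
        nn.MaxPool2D((2, 2)),
    ]
    expansion = 6
    for cin, cout in plan:
        body = nn.Sequential(
            [
                nn.Conv2D(cin, cin * expansion, (1, 1), rng),
                nn.ReLU(),
                nn.DepthwiseConv2D(cin * expansion, (3, 3), rng),
                nn.ReLU(),
                nn.Conv2D(cin * expansion, cout, (1, 1), rng),
            ]
        )
        if cin == cout:
            layers.append(nn.Add(body))
        else:
            layers.append(body)
        # skip-maximizing refinement block at constant width
        refine = nn.Sequential(
            [
                nn.Conv2D(cout, cout * expansion, (1, 1), rng),
                nn.ReLU(),
                nn.DepthwiseConv2D(cout * expansion, (3, 3), rng),
                nn.ReLU(),
                nn.Conv2D(cout * expansion, cout, (1, 1), rng),
            ]
        )
        layers.append(nn.Add(refine))
        layers.append(nn.MaxPool2D((2, 2)))
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers), plan[-1][1]


_STREAMS = {
    "escape": _escape_stream,
    "residual": _residual_stream,
    "mobile": _mobile_stream,
}


class TwoStreamClassifier:
    """Parallel SE and TE feature extractors feeding a softmax head."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        builder = _STREAMS[spec.backbone]
        self.stream_se, feat = builder(spec, self.rng)
        self.stream_te, _ = builder(spec, self.rng)
        head_layers: list[nn.Layer] = []
        if spec.backbone == "escape":
            head_layers.append(nn.Dropout(spec.dropout, self.rng))
        head_layers.append(nn.Dense(2 * feat, spec.n_classes, self.rng))
        self.head = nn.Sequential(head_layers)
        self._feat = feat

    # -- forward / backward -------------------------------------------------
    def forward(self, x_se: np.ndarray, x_te: np.ndarray, train: bool = False) -> np.ndarray:
        f1 = self.stream_se.forward(x_se, train=train)
        f2 = self.stream_te.forward(x_te, train=train)
        return self.head.forward(np.concatenate([f1, f2], axis=1), train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        self.stream_se.backward(g[:, : self._feat])
        self.stream_te.backward(g[:, self._feat :])

    # -- parameters ---------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return self.stream_se.params + self.stream_te.params + self.head.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.stream_se.grads + self.stream_te.grads + self.head.grads

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def predict_proba(self, x_se: np.ndarray, x_te: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x_se.shape[0], batch_size):
            logits = self.forward(x_se[i : i + batch_size], x_te[i : i + batch_size], train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)


def build_model(spec: ModelSpec, seed: int = 0) -> TwoStreamClassifier:
    """Instantiate an untrained two-stream classifier (seeded weights)."""
    return TwoStreamClassifier(spec, seed=seed)


def escape_parameter_count(spec: ModelSpec) -> int:
    """Analytic parameter count of the escape backbone for ``spec``.

    Counts conv kernels+biases, the per-stream dense layer, and the head,
    mirroring the documented layer plan; used as an independent check of
    the constructed network.
    """
    c1, c2 = _ch(64, spec.width_mult), _ch(128, spec.width_mult)
    dense = _ch(1024, spec.width_mult)
    h, w = spec.input_shape
    h2, w2 = h // 4, w // 4
    stream = (
        c1 * (1 * 5 * 5) + c1
        + c2 * (c1 * 3 * 3) + c2
        + (h2 * w2 * c2) * dense + dense
    )
    head = (2 * dense) * spec.n_classes + spec.n_classes
    return 2 * stream + head


@dataclasses.dataclass
class TrainedModel:
    model: TwoStreamClassifier
    history: dict[str, list[float]]
    config: TrainConfig
    best_epoch: int

    def predict(self, x_se: np.ndarray, x_te: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        proba = self.model.predict_proba(x_se, x_te)
        return proba, proba.argmax(axis=1)


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train(
    model: TwoStreamClassifier,
    x_se: np.ndarray,
    x_te: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """SGD training with early stopping on a stratified validation split.

    Stops when the validation loss has not improved for ``patience`` epochs
    (or at ``max_epochs``) and restores the best-validation-loss weights.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ModelError("degenerate labels: need at least two classes")
    if labels.min() < 0 or labels.max() >= model.spec.n_classes:
        raise ModelError("labels outside [0, n_classes)")
    rng = np.random.default_rng(config.seed)
    model.rng = np.random.default_rng(rng.integers(2**31))  # dropout stream
    tr, va = _stratified_split(labels, config.val_fraction, rng)
    if va.size == 0:
        raise ModelError("validation split is empty")
    opt = nn.SGD(
        model.params,
        model.grads,
        lr=config.learning_rate,
        decay=config.lr_decay,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    x_se = x_se.astype(np.float32, copy=False)
    x_te = x_te.astype(np.float32, copy=False)
    history: dict[str, list[float]] = {"loss": [], "val_loss": [], "val_accuracy": []}
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), -1
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses = []
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x_se[idx], x_te[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_proba = model.predict_proba(x_se[va], x_te[va])
        val_pred = val_proba.argmax(axis=1)
        val_loss = float(
            -np.log(np.clip(val_proba[np.arange(va.size), labels[va]], 1e-12, None)).mean()
        )
        val_acc = float((val_pred == labels[va]).mean())
        history["loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if verbose:
            print(
                f"epoch {epoch}: loss {history['loss'][-1]:.4f} "
                f"val_loss {val_loss:.4f} val_acc {val_acc:.4f}",
                flush=True,
            )
        if val_loss < best_loss:
            best_loss, best_weights, best_epoch = val_loss, model.get_weights(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_weights(best_weights)
    return TrainedModel(model=model, history=history, config=config, best_epoch=best_epoch)


def predict(
    trained: TrainedModel | TwoStreamClassifier, x_se: np.ndarray, x_te: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (deterministic: dropout off)."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    h, w = model.spec.input_shape
    if x_se.shape[1:] != (1, h, w) or x_te.shape[1:] != (1, h, w):
        raise ModelError(f"expected batches of shape (n, 1, {h}, {w})")
    proba = model.predict_proba(
        x_se.astype(np.float32, copy=False), x_te.astype(np.float32, copy=False)
    )
    return proba, proba.argmax(axis=1)
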