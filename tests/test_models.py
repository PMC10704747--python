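"""Two-stream CNN construction, gradients, training protocol tests."""

from __future__ import annotations

import numpy as np
import pytest

from cuffsim import models as M
from cuffsim import nn


def _toy_batch(rng, n, shape=(8, 12)):
    return (
        rng.normal(size=(n, 1, *shape)).astype(np.float32),
        rng.normal(size=(n, 1, *shape)).astype(np.float32),
    )


def _separable_dataset(rng, n_per_class, n_classes, shape=(8, 12)):
    """Classes distinguished by a strong mean shift in one corner patch."""
    xs, ys = [], []
    for c in range(n_classes):
        x = rng.normal(size=(n_per_class, 1, *shape)).astype(np.float32)
        x[:, 0, :3, :3] += 3.0 * (c + 1)
        xs.append(x)
        ys.append(np.full(n_per_class, c))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = rng.permutation(y.size)
    return x[order], x[order] * 0.5, y[order]


class TestBuildModel:
    def test_softmax_output_normalized(self):
        net = M.build_model(M.ModelSpec.desk(n_classes=5), seed=0)
        xs = np.random.default_rng(0).normal(size=(3, 1, 56, 100)).astype(np.float32)
        proba = net.predict_proba(xs, xs)
        assert proba.shape == (3, 5)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_full_width_parameter_ranking(self):
        counts = {}
        for backbone in ("escape", "residual", "mobile"):
            net = M.build_model(M.ModelSpec(backbone=backbone, n_classes=3), seed=0)
            counts[backbone] = net.n_params()
            del net
        assert counts["escape"] > counts["residual"] > counts["mobile"]
        # escape's full-width count sits in the ~90M range
        assert 8e7 < counts["escape"] < 1.1e8

    def test_desk_escape_matches_analytic_count(self):
        spec = M.ModelSpec.desk(n_classes=3)
        net = M.build_model(spec, seed=0)
        assert net.n_params() == M.escape_parameter_count(spec)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(M.ModelError):
            M.ModelSpec(backbone="transformer")

    @pytest.mark.parametrize("backbone", ["escape", "residual", "mobile"])
    def test_gradients_match_finite_differences(self, backbone):
        spec = M.ModelSpec(
            backbone=backbone,
            n_classes=3,
            width_mult=1 / 32,
            dropout=0.0,
            input_shape=(8, 12),
        )
        net = M.build_model(spec, seed=1)
        rng = np.random.default_rng(0)
        # nudge every parameter (esp. zero-initialized biases) so no
        # pre-activation sits exactly on a ReLU kink, where the analytic
        # subgradient and a finite difference legitimately disagree
        for p in net.params:
            p += rng.normal(0, 0.02, size=p.shape).astype(np.float32)
        xs, xt = _toy_batch(rng, 4)
        y = np.array([0, 1, 2, 0])
        logits = net.forward(xs, xt, train=True)
        _, dl = nn.softmax_cross_entropy(logits, y)
        net.backward(dl)
        # directional derivative check: aggregate over all parameters so
        # float32 forward noise and single-weight ReLU kinks average out
        rng_d = np.random.default_rng(2)
        direction = [rng_d.normal(size=p.shape).astype(np.float32) for p in net.params]
        norm = np.sqrt(sum((d**2).sum() for d in direction))
        direction = [d / norm for d in direction]
        analytic = float(sum((g * d).sum() for g, d in zip(net.grads, direction)))
        eps = 2e-3
        originals = [p.copy() for p in net.params]
        for p, d in zip(net.params, direction):
            p += eps * d
        l1, _ = nn.softmax_cross_entropy(net.forward(xs, xt), y)
        for p, o, d in zip(net.params, originals, direction):
            p[...] = o - eps * d
        l2, _ = nn.softmax_cross_entropy(net.forward(xs, xt), y)
        for p, o in zip(net.params, originals):
            p[...] = o
        numeric = (l1 - l2) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=0.05, abs=1e-4)


class TestTrain:
    def test_overfits_separable_toy_data(self):
        rng = np.random.default_rng(2)
        xs, xt, y = _separable_dataset(rng, 24, 2)
        spec = M.ModelSpec(
            backbone="escape", n_classes=2, width_mult=1 / 32, input_shape=(8, 12)
        )
        net = M.build_model(spec, seed=0)
        cfg = M.TrainConfig(
            learning_rate=0.02,
            momentum=0.9,
            batch_size=16,
            max_epochs=200,
            patience=200,
            seed=0,
        )
        trained = M.train(net, xs, xt, y, cfg)
        _, pred = trained.predict(xs, xt)
        assert np.mean(pred == y) == 1.0

    def test_early_stopping_contract(self):
        rng = np.random.default_rng(3)
        xs, xt, y = _separable_dataset(rng, 16, 2)
        spec = M.ModelSpec(
            backbone="escape", n_classes=2, width_mult=1 / 32, input_shape=(8, 12)
        )
        net = M.build_model(spec, seed=0)
        cfg = M.TrainConfig(
            learning_rate=1e4,  # deliberately diverging
            patience=1,
            max_epochs=50,
            batch_size=16,
            seed=0,
        )
        with np.errstate(over="ignore", invalid="ignore"):
            trained = M.train(net, xs, xt, y, cfg)
        assert len(trained.history["val_loss"]) <= 5

    def test_backbone_patience_defaults(self):
        assert M.TrainConfig.for_backbone("escape").patience == 15
        assert M.TrainConfig.for_backbone("residual").patience == 40
        assert M.TrainConfig.for_backbone("mobile").patience == 40

    def test_single_class_rejected(self):
        rng = np.random.default_rng(4)
        xs, xt = _toy_batch(rng, 8)
        net = M.build_model(
            M.ModelSpec(backbone="escape", n_classes=2, width_mult=1 / 32,
                        input_shape=(8, 12)),
            seed=0,
        )
        with pytest.raises(M.ModelError, match="degenerate"):
            M.train(net, xs, xt, np.zeros(8, dtype=int))

    def test_shuffled_labels_give_chance_accuracy(self):
        """Leakage guard: random labels cannot be predicted above chance."""
        rng = np.random.default_rng(5)
        n = 300
        xs, xt = _toy_batch(rng, n)
        y = rng.integers(0, 2, n)
        spec = M.ModelSpec(
            backbone="escape", n_classes=2, width_mult=1 / 32, input_shape=(8, 12)
        )
        net = M.build_model(spec, seed=0)
        cfg = M.TrainConfig(max_epochs=5, batch_size=32, seed=0)
        trained = M.train(net, xs[:200], xt[:200], y[:200], cfg)
        _, pred = trained.predict(xs[200:], xt[200:])
        acc = np.mean(pred == y[200:])
        se = np.sqrt(0.25 / 100)
        assert abs(acc - 0.5) < 3 * se

    def test_training_reproducible_under_seed(self):
        rng = np.random.default_rng(6)
        xs, xt, y = _separable_dataset(rng, 12, 2)
        spec = M.ModelSpec(
            backbone="escape", n_classes=2, width_mult=1 / 32, input_shape=(8, 12)
        )
        cfg = M.TrainConfig(max_epochs=3, batch_size=16, seed=7)
        t1 = M.train(M.build_model(spec, seed=1), xs, xt, y, cfg)
        t2 = M.train(M.build_model(spec, seed=1), xs, xt, y, cfg)
        assert t1.history["val_loss"] == t2.history["val_loss"]
        for a, b in zip(t1.model.params, t2.model.params):
            assert np.array_equal(a, b)


class TestPredict:
    def test_eval_deterministic(self):
        net = M.build_model(M.ModelSpec.desk(n_classes=3), seed=0)
        rng = np.random.default_rng(0)
        xs = rng.normal(size=(4, 1, 56, 100)).astype(np.float32)
        p1, l1 = M.predict(net, xs, xs)
        p2, l2 = M.predict(net, xs, xs)
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)

    def test_argmax_consistent_with_probabilities(self):
        net = M.build_model(M.ModelSpec.desk(n_classes=4), seed=1)
        rng = np.random.default_rng(1)
        xs = rng.normal(size=(6, 1, 56, 100)).astype(np.float32)
        proba, labels = M.predict(net, xs, xs)
        assert np.array_equal(labels, proba.argmax(axis=1))

    def test_shape_mismatch_rejected(self):
        net = M.build_model(M.ModelSpec.desk(n_classes=3), seed=0)
        with pytest.raises(M.ModelError):
            M.predict(net, np.zeros((2, 1, 10, 10)), np.zeros((2, 1, 10, 10)))

    def test_hand_set_head_implements_linear_rule(self):
        """Zeroed streams + hand-set head bias reduce predict to argmax(b)."""
        spec = M.ModelSpec(
            backbone="escape", n_classes=3, width_mult=1 / 32, input_shape=(8, 12)
        )
        net = M.build_model(spec, seed=0)
        for p in net.stream_se.params + net.stream_te.params:
            p[...] = 0.0
        head = net.head.layers[-1]
        head.W[...] = 0.0
        head.b[...] = np.array([0.1, 0.9, -0.4], dtype=np.float32)
        rng = np.random.default_rng(2)
        for _ in range(10):
            xs = rng.normal(size=(1, 1, 8, 12)).astype(np.float32)
            _, label = M.predict(net, xs, xs)
            assert label[0] == 1

    def test_dropout_only_active_in_training(self):
        spec = M.ModelSpec.desk(n_classes=3)
        net = M.build_model(spec, seed=0)
        rng = np.random.default_rng(3)
        xs = rng.normal(size=(2, 1, 56, 100)).astype(np.float32)
        e1 = net.forward(xs, xs, train=False)
        e2 = net.forward(xs, xs, train=False)
        assert np.array_equal(e1, e2)
        t1 = net.forward(xs, xs, train=True)
        t2 = net.forward(xs, xs, train=True)
        assert not np.array_equal(t1, t2)


class TestClassPermutationEquivariance:
    def test_permuting_labels_permutes_confusion(self):
        rng = np.random.default_rng(8)
        xs, xt, y = _separable_dataset(rng, 20, 3)
        spec = M.ModelSpec(
            backbone="escape", n_classes=3, width_mult=1 / 32, input_shape=(8, 12)
        )
        cfg = M.TrainConfig(
            learning_rate=0.02, momentum=0.9, batch_size=16, max_epochs=100,
            patience=100, seed=0,
        )
        perm = np.array([2, 0, 1])
        t1 = M.train(M.build_model(spec, seed=1), xs, xt, y, cfg)
        t2 = M.train(M.build_model(spec, seed=1), xs, xt, perm[y], cfg)
        _, p1 = t1.predict(xs, xt)
        _, p2 = t2.predict(xs, xt)
        agree = np.mean(perm[p1] == p2)
        assert agree > 0.8
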