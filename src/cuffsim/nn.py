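"""Minimal CNN building blocks in NumPy with numba kernels.

Implements exactly what the two-stream signature classifiers need:
2-D convolution, depthwise convolution, max pooling, dense, dropout,
ReLU, global average pooling, residual and inverted-bottleneck blocks,
softmax cross-entropy, and a Keras-legacy-style SGD (learning-rate decay
``lr / (1 + decay * t)`` plus classical momentum).  Convolution and
pooling inner loops are JIT-compiled (row-contiguous accumulation,
unit stride, 'same' or 'valid' padding); everything computes in float32.

Gradients are exact; see ``tests`` for finite-difference checks.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(fastmath=True, cache=True)
def _conv_fwd(xp, W, out):  # pragma: no cover - exercised via Conv2D
    B, C, _, _ = xp.shape
    O, _, kh, kw = W.shape
    _, _, Ho, Wo = out.shape
    for b in range(B):
        for o in range(O):
            for i in range(Ho):
                acc = out[b, o, i]
                for c in range(C):
                    for u in range(kh):
                        row = xp[b, c, i + u]
                        for v in range(kw):
                            w = W[o, c, u, v]
                            for j in range(Wo):
                                acc[j] += w * row[j + v]


@numba.njit(fastmath=True, cache=True)
def _conv_dw(xp, grad, dW):  # pragma: no cover
    B, C, _, _ = xp.shape
    O, _, kh, kw = dW.shape
    _, _, Ho, Wo = grad.shape
    for b in range(B):
        for o in range(O):
            for i in range(Ho):
                grow = grad[b, o, i]
                for c in range(C):
                    for u in range(kh):
                        row = xp[b, c, i + u]
                        for v in range(kw):
                            acc = np.float32(0.0)
                            for j in range(Wo):
                                acc += grow[j] * row[j + v]
                            dW[o, c, u, v] += acc


@numba.njit(fastmath=True, cache=True)
def _conv_dx(dxp, grad, W):  # pragma: no cover
    B, C, _, _ = dxp.shape
    O, _, kh, kw = W.shape
    _, _, Ho, Wo = grad.shape
    for b in range(B):
        for o in range(O):
            for i in range(Ho):
                grow = grad[b, o, i]
                for c in range(C):
                    for u in range(kh):
                        drow = dxp[b, c, i + u]
                        for v in range(kw):
                            w = W[o, c, u, v]
                            for j in range(Wo):
                                drow[j + v] += w * grow[j]


@numba.njit(fastmath=True, cache=True)
def _dwconv_fwd(xp, W, out):  # pragma: no cover
    B, C, _, _ = xp.shape
    _, kh, kw = W.shape
    _, _, Ho, Wo = out.shape
    for b in range(B):
        for c in range(C):
            for i in range(Ho):
                acc = out[b, c, i]
                for u in range(kh):
                    row = xp[b, c, i + u]
                    for v in range(kw):
                        w = W[c, u, v]
                        for j in range(Wo):
                            acc[j] += w * row[j + v]


@numba.njit(fastmath=True, cache=True)
def _dwconv_dw_dx(xp, grad, W, dW, dxp):  # pragma: no cover
    B, C, _, _ = xp.shape
    _, kh, kw = W.shape
    _, _, Ho, Wo = grad.shape
    for b in range(B):
        for c in range(C):
            for i in range(Ho):
                grow = grad[b, c, i]
                for u in range(kh):
                    row = xp[b, c, i + u]
                    drow = dxp[b, c, i + u]
                    for v in range(kw):
                        w = W[c, u, v]
                        acc = np.float32(0.0)
                        for j in range(Wo):
                            acc += grow[j] * row[j + v]
                            drow[j + v] += w * grow[j]
                        dW[c, u, v] += acc


@numba.njit(fastmath=True, cache=True)
def _pool_fwd(x, out, arg, ph, pw):  # pragma: no cover
    B, C, Ho, Wo = out.shape
    for b in range(B):
        for c in range(C):
            for i in range(Ho):
                for j in range(Wo):
                    best = x[b, c, i * ph, j * pw]
                    bidx = 0
                    for u in range(ph):
                        for v in range(pw):
                            val = x[b, c, i * ph + u, j * pw + v]
                            if val > best:
                                best = val
                                bidx = u * pw + v
                    out[b, c, i, j] = best
                    arg[b, c, i, j] = bidx


@numba.njit(fastmath=True, cache=True)
def _pool_bwd(dx, grad, arg, ph, pw):  # pragma: no cover
    B, C, Ho, Wo = grad.shape
    for b in range(B):
        for c in range(C):
            for i in range(Ho):
                for j in range(Wo):
                    idx = arg[b, c, i, j]
                    dx[b, c, i * ph + idx // pw, j * pw + idx % pw] = grad[b, c, i, j]


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D(Layer):
    """Same- or valid-padding 2-D convolution over (B, C, H, W) tensors."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        padding: str = "same",
        input_grad: bool = True,
    ) -> None:
        kh, kw = kernel
        self.kh, self.kw = kh, kw
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.input_grad = input_grad  # False for a network's first layer
        fan_in = in_channels * kh * kw
        self.W = _he_init(rng, (out_channels, in_channels, kh, kw), fan_in)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _pad(self) -> tuple[int, int, int, int]:
        if self.padding == "valid":
            return (0, 0, 0, 0)
        ph, pw = self.kh - 1, self.kw - 1
        return (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pt, pb, pl, pr = self._pad()
        xp = np.ascontiguousarray(
            np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))), dtype=np.float32
        )
        B, C, Hp, Wp = xp.shape
        Ho = Hp - self.kh + 1
        Wo = Wp - self.kw + 1
        self._xp = xp
        self._xshape = x.shape
        out = np.zeros((B, self.out_channels, Ho, Wo), dtype=np.float32)
        _conv_fwd(xp, self.W, out)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        self.dW[...] = 0.0
        _conv_dw(self._xp, grad, self.dW)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        if not self.input_grad:
            return np.zeros(self._xshape, dtype=grad.dtype)
        pt, pb, pl, pr = self._pad()
        dxp = np.zeros_like(self._xp)
        _conv_dx(dxp, grad, self.W)
        _, C, H, W = self._xshape
        return dxp[:, :, pt : pt + H, pl : pl + W]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def n_params(self) -> int:
        return self.W.size + self.b.size


class DepthwiseConv2D(Layer):
    """Per-channel (depthwise) same-padding convolution."""

    def __init__(
        self, channels: int, kernel: tuple[int, int], rng: np.random.Generator
    ) -> None:
        self.kh, self.kw = kernel
        self.channels = channels
        fan_in = self.kh * self.kw
        self.W = _he_init(rng, (channels, self.kh, self.kw), fan_in)
        self.b = np.zeros(channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        ph, pw = self.kh - 1, self.kw - 1
        self._pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        pt, pb, pl, pr = self._pads
        xp = np.ascontiguousarray(
            np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))), dtype=np.float32
        )
        self._xp = xp
        self._xshape = x.shape
        B = x.shape[0]
        out = np.zeros((B, self.channels) + x.shape[2:], dtype=np.float32)
        _dwconv_fwd(xp, self.W, out)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        self.dW[...] = 0.0
        dxp = np.zeros_like(self._xp)
        _dwconv_dw_dx(self._xp, grad, self.W, self.dW, dxp)
        pt, pb, pl, pr = self._pads
        _, C, H, W = self._xshape
        return dxp[:, :, pt : pt + H, pl : pl + W]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    def __init__(self, pool: tuple[int, int]) -> None:
        self.ph, self.pw = pool

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        ph, pw = self.ph, self.pw
        self._shape = x.shape
        x = np.ascontiguousarray(x, dtype=np.float32)
        out = np.empty((B, C, H // ph, W // pw), dtype=np.float32)
        self._arg = np.empty(out.shape, dtype=np.int8)
        _pool_fwd(x, out, self._arg, ph, pw)
        return out

    def backward(self, grad):
        dx = np.zeros(self._shape, dtype=np.float32)
        _pool_bwd(dx, np.ascontiguousarray(grad, dtype=np.float32), self._arg, self.ph, self.pw)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _he_init(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` is True."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]


class Residual(Layer):
    """Identity-skip block: out = relu(body(x) + x)."""

    def __init__(self, body: Sequential):
        self.body = body
        self.relu = ReLU()

    def forward(self, x, train=False):
        return self.relu.forward(self.body.forward(x, train=train) + x, train=train)

    def backward(self, grad):
        g = self.relu.backward(grad)
        return self.body.backward(g) + g

    @property
    def params(self):
        return self.body.params

    @property
    def grads(self):
        return self.body.grads


class Add(Layer):
    """Skip-add wrapper used by inverted-bottleneck blocks."""

    def __init__(self, body: Sequential):
        self.body = body

    def forward(self, x, train=False):
        return self.body.forward(x, train=train) + x

    def backward(self, grad):
        return self.body.backward(grad) + grad

    @property
    def params(self):
        return self.body.params

    @property
    def grads(self):
        return self.body.grads


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class SGD:
    """Classical momentum SGD with Keras-legacy learning-rate decay.

    Effective rate at update t is ``lr / (1 + decay * t)``; the velocity
    update is ``v = momentum * v - lr_t * grad`` followed by ``w += v``.
    Optional L2 weight decay is applied as an additive gradient term.
    """

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        decay: float = 1e-6,
        momentum: float = 1e-9,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.decay = decay
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.iterations = 0
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        lr_t = self.lr / (1.0 + self.decay * self.iterations)
        for p, g, v in zip(self.params, self.grads, self.velocity):
            gt = g if self.weight_decay == 0 else g + self.weight_decay * p
            v *= self.momentum
            v -= lr_t * gt
            p += v
        self.iterations += 1
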