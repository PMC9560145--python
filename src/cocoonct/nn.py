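"""Minimal numpy engine for small 3D convolutional networks.

Implements exactly the pieces the cocoon segmenter needs — 3D convolution
(arbitrary stride), stride-matched transposed convolution, batch
normalization, PReLU, softmax and a soft-Dice loss — each as a layer with an
explicit, hand-derived ``backward``.  Convolutions are evaluated by the
shift-and-accumulate scheme (one small matrix product per kernel offset),
which keeps memory at the size of the feature maps and routes the arithmetic
through BLAS.  All layers operate on ``(N, C, D, H, W)`` float32 arrays.

Gradient correctness is pinned down by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("val", "grad", "name")

    def __init__(self, val: np.ndarray, name: str = "") -> None:
        self.val = np.asarray(val, dtype=DTYPE)
        self.grad = np.zeros_like(self.val)
        self.name = name


class Layer:
    """Base class: stateless API, caches kept between forward and backward."""

    def params(self) -> Iterator[Param]:
        return iter(())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(k: int):
    return itertools.product(range(k), range(k), range(k))


class Conv3d(Layer):
    """3D convolution, kernel ``k``^3, zero padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s = kernel, stride
        self.p = (kernel // 2) if padding is None else padding
        fan_in = in_ch * kernel ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel, kernel))
        self.w = Param(w, "conv.w")
        self.b = Param(np.zeros(out_ch), "conv.b") if bias else None
        self._cache = None

    def params(self):
        yield self.w
        if self.b is not None:
            yield self.b

    def _out_shape(self, d: int) -> int:
        return (d + 2 * self.p - self.k) // self.s + 1

    def forward(self, x, training=False):
        k, s, p = self.k, self.s, self.p
        n, c, d, h, w = x.shape
        do, ho, wo = (self._out_shape(v) for v in (d, h, w))
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        y = np.zeros((n, self.out_ch, do, ho, wo), dtype=x.dtype)
        for i, j, l in _offsets(k):
            xs = xp[:, :, i:i + do * s:s, j:j + ho * s:s, l:l + wo * s:s]
            # (O,C) x (N,C,D',H',W') -> (O,N,D',H',W')
            y += np.moveaxis(np.tensordot(self.w.val[:, :, i, j, l], xs, axes=([1], [1])), 0, 1)
        if self.b is not None:
            y += self.b.val[None, :, None, None, None]
        self._cache = (xp, x.shape, (do, ho, wo))
        return y

    def backward(self, dy):
        xp, x_shape, (do, ho, wo) = self._cache
        k, s, p = self.k, self.s, self.p
        dxp = np.zeros_like(xp)
        for i, j, l in _offsets(k):
            sl = (slice(None), slice(None),
                  slice(i, i + do * s, s), slice(j, j + ho * s, s), slice(l, l + wo * s, s))
            xs = xp[sl]
            self.w.grad[:, :, i, j, l] += np.tensordot(dy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            dxp[sl] += np.moveaxis(
                np.tensordot(self.w.val[:, :, i, j, l], dy, axes=([0], [1])), 0, 1)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        n, c, d, h, w = x_shape
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel == stride (non-overlapping upsampling).

    Each input voxel expands to a ``k``^3 output block, the exact adjoint of a
    stride-``k`` convolution; this avoids checkerboard overlap entirely.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 2,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch, kernel, kernel, kernel))
        self.w = Param(w, "upconv.w")
        self.b = Param(np.zeros(out_ch), "upconv.b")
        self._x = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x, training=False):
        k = self.k
        n, c, d, h, w = x.shape
        y = np.empty((n, self.out_ch, d * k, h * k, w * k), dtype=x.dtype)
        for i, j, l in _offsets(k):
            y[:, :, i::k, j::k, l::k] = np.moveaxis(
                np.tensordot(self.w.val[:, :, i, j, l], x, axes=([0], [1])), 0, 1)
        y += self.b.val[None, :, None, None, None]
        self._x = x
        return y

    def backward(self, dy):
        k = self.k
        x = self._x
        dx = np.zeros_like(x)
        for i, j, l in _offsets(k):
            dys = dy[:, :, i::k, j::k, l::k]
            self.w.grad[:, :, i, j, l] += np.tensordot(x, dys, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            dx += np.moveaxis(np.tensordot(self.w.val[:, :, i, j, l], dys, axes=([1], [1])), 0, 1)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        return dx


class BatchNorm3d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(ch), "bn.gamma")
        self.beta = Param(np.zeros(ch), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache = None

    def params(self):
        yield self.gamma
        yield self.beta

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        self._cache = (xhat, invstd, training)
        return self.gamma.val[None, :, None, None, None] * xhat + self.beta.val[None, :, None, None, None]

    def backward(self, dy):
        xhat, invstd, training = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.val[None, :, None, None, None]
        dxhat = dy * g
        if not training:
            return dxhat * invstd[None, :, None, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        mean_dxhat = dxhat.mean(axis=axes)[None, :, None, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes)[None, :, None, None, None]
        return invstd[None, :, None, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative slope per channel."""

    def __init__(self, ch: int, init: float = 0.25) -> None:
        self.a = Param(np.full(ch, init), "prelu.a")
        self._x = None

    def params(self):
        yield self.a

    def forward(self, x, training=False):
        self._x = x
        a = self.a.val[None, :, None, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, dy):
        x = self._x
        a = self.a.val[None, :, None, None, None]
        neg = x <= 0
        self.a.grad += (dy * np.where(neg, x, 0.0)).sum(axis=(0, 2, 3, 4))
        return dy * np.where(neg, a, 1.0)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    zmax = z.max(axis=axis, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N,D,H,W) integer labels -> (N,C,D,H,W) float32 one-hot."""
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=DTYPE)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def dice_loss(probs: np.ndarray, target: np.ndarray, smooth: float = 1e-5,
              include_background: bool = False) -> float:
    """Soft-Dice loss: 1 - mean over classes of (2*sum(p*g)+s)/(sum(p)+sum(g)+s).

    Sums run over the whole batch and all voxels (one global Dice per class).
    Background (class 0) is excluded by default.
    """
    loss, _ = _dice_loss_grad(probs, target, smooth, include_background, want_grad=False)
    return loss


def _dice_loss_grad(probs, target, smooth, include_background, want_grad=True):
    if probs.size == 0:
        raise ValueError("empty input to dice loss")
    classes = range(probs.shape[1]) if include_background else range(1, probs.shape[1])
    classes = list(classes)
    dprobs = np.zeros_like(probs) if want_grad else None
    total = 0.0
    axes = (0, 2, 3, 4)
    for c in classes:
        p, g = probs[:, c], target[:, c]
        inter = float((p * g).sum())
        denom = float(p.sum() + g.sum())
        total += (2.0 * inter + smooth) / (denom + smooth)
        if want_grad:
            num = 2.0 * inter + smooth
            den = denom + smooth
            dprobs[:, c] = -(2.0 * g * den - num) / (den * den) / len(classes)
    return 1.0 - total / len(classes), dprobs


def softmax_dice_loss(logits: np.ndarray, labels: np.ndarray, n_classes: int,
                      smooth: float = 1e-5, include_background: bool = False):
    """Loss and gradient w.r.t. logits for integer-labelled voxels."""
    probs = softmax(logits)
    target = one_hot(labels, n_classes)
    loss, dprobs = _dice_loss_grad(probs, target, smooth, include_background)
    # softmax Jacobian: dz = p * (dp - sum_c dp_c p_c)
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    dlogits = probs * (dprobs - inner)
    return loss, dlogits.astype(logits.dtype)


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to grads."""

    def __init__(self, params: list[Param], lr: float = 1e-4, weight_decay: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.val) for p in self.params]
        self.v = [np.zeros_like(p.val) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.wd:
                g = g + self.wd * p.val
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.val -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
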