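"""Minimal CPU neural-network layers with explicit backpropagation.

Activations are float32 arrays in NHWC layout (batch, height, width,
channel); convolutions are lowered to a single BLAS GEMM per call through an
offset-copy im2col in that layout, which is what makes desk-scale training
of the residual U-Net practical on one core. Every layer caches exactly the
arrays its backward pass needs; ``im2col`` buffers are recomputed in the
backward pass instead of cached, trading a little compute for a large
reduction in peak memory.

All randomness flows through explicitly passed ``numpy.random.Generator``
objects, so training is bit-reproducible for a fixed seed and thread count.
"""
from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9*C) patches of the zero-padded 3x3 neighborhood.

    Column order is (ky, kx, c) with the channel fastest, matching the
    weight layout of :class:`Conv2d`.
    """
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
    xp[:, 1:-1, 1:-1, :] = x
    buf = np.empty((n, h, w, 9, c), dtype=np.float32)
    i = 0
    for ky in range(3):
        for kx in range(3):
            buf[:, :, :, i, :] = xp[:, ky:ky + h, kx:kx + w, :]
            i += 1
    return buf.reshape(n * h * w, 9 * c)


class Conv2d(Module):
    """3x3 (or 1x1) same-padding convolution, stride 1, with bias.

    Weights use He/Kaiming normal initialization scaled by fan-in.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = k * k * cin
        w = rng.standard_normal((k * k * cin, cout)) * np.sqrt(2.0 / fan_in)
        self.W = Param(w)
        self.b = Param(np.zeros(cout))
        self.x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        n, h, w, _ = x.shape
        if self.k == 1:
            y = x.reshape(-1, self.cin) @ self.W.value
        else:
            y = _im2col3(x) @ self.W.value
        y += self.b.value
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(-1, self.cout)
        self.b.grad += dyf.sum(axis=0)
        if self.k == 1:
            xf = self.x.reshape(-1, self.cin)
            self.W.grad += xf.T @ dyf
            dx = dyf @ self.W.value.T
            return dx.reshape(self.x.shape)
        col = _im2col3(self.x)
        self.W.grad += col.T @ dyf
        # grad wrt input = convolution of dy with the spatially flipped
        # kernel and swapped in/out channels
        wr = self.W.value.reshape(3, 3, self.cin, self.cout)
        wr = wr[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.cout, self.cin)
        dx = _im2col3(dyf.reshape(n, h, w, self.cout)) @ wr
        return dx.reshape(self.x.shape)


class GroupNorm(Module):
    """Group normalization over (H, W, C_group) per sample; batch-size
    independent and deterministic, with per-channel affine parameters."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        while channels % groups:
            groups //= 2
        self.c, self.g, self.eps = channels, max(groups, 1), eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self):
        return [self.gamma, self.beta]

    def _grouped(self, x):
        n, h, w, c = x.shape
        return x.reshape(n, h * w, self.g, c // self.g)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xg = self._grouped(x)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        self.inv = 1.0 / np.sqrt(var + self.eps)
        self.xhat = ((xg - mu) * self.inv).reshape(x.shape).astype(np.float32)
        return self.xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gamma.grad += (dy * self.xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = self._grouped(dy * self.gamma.value)
        xhat = self._grouped(self.xhat)
        m1 = dxhat.mean(axis=(1, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 3), keepdims=True)
        dx = (dxhat - m1 - xhat * m2) * self.inv
        return dx.reshape(dy.shape).astype(np.float32)


class ReLU(Module):
    def forward(self, x):
        self.mask = x > 0
        return np.where(self.mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self.mask, dy, 0.0).astype(np.float32)


class MaxPool2(Module):
    """2x2 max pooling, stride 2. Input spatial dims must be even."""

    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self.idx = xr.argmax(axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(xr, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self.in_shape
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(g, self.idx[..., None], dy[..., None], axis=-1)
        g = g.reshape(n, h // 2, w // 2, c, 2, 2)
        return g.transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c).copy()


class Upsample2(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean pixel-wise cross-entropy over class logits (N,H,W,K) against
    integer targets (N,H,W). Returns (loss, dlogits, probabilities)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    n = targets.size
    flat = probs.reshape(n, -1)
    idx = targets.reshape(-1)
    picked = flat[np.arange(n), idx]
    loss = float(-np.mean(np.log(np.maximum(picked, 1e-12))))
    dlogits = probs.copy()
    d = dlogits.reshape(n, -1)
    d[np.arange(n), idx] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(np.float32), probs


class Adam:
    """Adaptive-moment optimizer with the standard defaults."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
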