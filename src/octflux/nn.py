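"""Minimal numpy neural-network layers with hand-written backpropagation.

Implements exactly the pieces the flux regressor needs — 1D convolution
(im2col + GEMM), batch normalization, ReLU, stride-1 max pooling, channel
concatenation, global average pooling and a dense head — plus the Adam
optimizer with global gradient-norm clipping.  All layers follow the same
contract:

* ``forward(x, training)`` caches what backward needs,
* ``backward(grad)`` accumulates parameter gradients in ``.grads`` and
  returns the gradient with respect to the input,
* ``params`` / ``grads`` are parallel lists of arrays.

Shapes are ``(batch, channels, length)`` throughout.  Correctness of every
backward pass is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1dSame",
    "GlobalAvgPool1d",
    "Dense",
    "Adam",
    "global_norm_clip",
]


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1D convolution.

    Computed as a sum of k shifted batched matmuls on strided views — on
    CPU this avoids the large im2col materialization and is markedly faster
    for the kernel sizes used here.  Weights are stored as
    ``(c_out, c_in, kernel)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        # He initialization for the ReLU-heavy network
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dw, self.db]
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2

    def forward(self, x, training=False):
        b, c, l = x.shape
        # channels-last contiguous buffer: every shifted slice below is then
        # unit-stride for BLAS
        xr = np.empty((b, l + self.kernel - 1, c), dtype=x.dtype)
        xr[:, : self.pad_left] = 0
        xr[:, self.pad_left : self.pad_left + l] = x.transpose(0, 2, 1)
        if self.pad_right:
            xr[:, self.pad_left + l :] = 0
        out = np.broadcast_to(self.b, (b, l, self.c_out)).copy()
        tmp = np.empty_like(out)
        for j in range(self.kernel):
            np.matmul(xr[:, j : j + l, :], self.w[:, :, j].T, out=tmp)
            out += tmp
        if training:
            self._xr, self._l = xr, l
        return out.transpose(0, 2, 1)

    def backward(self, grad):
        l = self._l
        g = np.ascontiguousarray(grad.transpose(0, 2, 1))  # (B, L, O)
        gt = g.transpose(0, 2, 1)  # (B, O, L), BLAS-friendly transpose of g
        self.db += g.sum(axis=(0, 1))
        dxr = np.zeros(self._xr.shape, dtype=grad.dtype)
        tmp = np.empty((g.shape[0], l, self.c_in), dtype=grad.dtype)
        for j in range(self.kernel):
            self.dw[:, :, j] += np.matmul(gt, self._xr[:, j : j + l, :]).sum(axis=0)
            np.matmul(g, self.w[:, :, j], out=tmp)
            dxr[:, j : j + l, :] += tmp
        self._xr = None
        return dxr[:, self.pad_left : self.pad_left + l, :].transpose(0, 2, 1)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if training:
            self._xhat, self._inv, self._n = xhat, inv, x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma += (grad * xhat).sum(axis=(0, 2))
        self.dbeta += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma[None, :, None]
        mean_g = gxhat.mean(axis=(0, 2), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
        self._xhat = None
        return inv[None, :, None] * (gxhat - mean_g - xhat * mean_gx)


class ReLU(Layer):
    params, grads = [], []

    def forward(self, x, training=False):
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool1dSame(Layer):
    """Stride-1 max pooling with same-length output."""

    params, grads = [], []

    def __init__(self, kernel: int = 3):
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2

    def forward(self, x, training=False):
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (self.pad_left, self.pad_right)),
            constant_values=-np.inf,
        )
        l = x.shape[2]
        out = xp[:, :, 0:l].copy()
        for j in range(1, self.kernel):
            np.maximum(out, xp[:, :, j : j + l], out=out)
        if training:
            self._xp = xp
            self._out = out
        return out

    def backward(self, grad):
        l = grad.shape[2]
        dxp = np.zeros(self._xp.shape, dtype=grad.dtype)
        claimed = np.zeros(grad.shape, dtype=bool)
        # route each gradient to the first window position attaining the max
        for j in range(self.kernel):
            m = (self._xp[:, :, j : j + l] == self._out) & ~claimed
            dxp[:, :, j : j + l] += np.where(m, grad, 0)
            claimed |= m
        self._xp = self._out = None
        return dxp[:, :, self.pad_left : self.pad_left + l]


class GlobalAvgPool1d(Layer):
    params, grads = [], []

    def forward(self, x, training=False):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._l, axis=2) / self._l


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dw, self.db]

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.dw += grad.T @ self._x
        self.db += grad.sum(axis=0)
        self._x = None
        return grad @ self.w


def global_norm_clip(grads, threshold: float) -> float:
    """Scale all gradients in place so their global L2 norm is <= threshold."""
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads)))
    if total > threshold and total > 0:
        scale = threshold / total
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adam optimizer over parallel lists of parameter and gradient arrays."""

    def __init__(self, params, grads, lr: float = 8e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0
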