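"""Minimal NumPy neural-network layers with explicit backprop.

Desk-scale building blocks (conv / batch-norm / ReLU / pooling / linear /
nearest upsampling) used by the staged classifier and the disc segmenter.
Tensors are ``(N, C, H, W)`` float32.  Every layer caches what its backward
pass needs; ``backward`` consumes the upstream gradient and accumulates
parameter gradients in ``.grads``.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "Upsample2x",
    "Sequential",
    "SGD",
    "sigmoid",
    "he_init",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols, xshape, k, stride, pad, ho, wo):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : h + pad, pad : w + pad]
    return dxp


class Layer:
    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        self.w = he_init(rng, (cout, cin * k * k), cin * k * k)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        self._xshape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._ho, self._wo = cols, ho, wo
        y = np.matmul(self.w, cols) + self.b[None, :, None]
        n = x.shape[0]
        return y.reshape(n, -1, ho, wo)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.reshape(n, dy.shape[1], -1)
        self.dw += np.einsum("ncl,nkl->ck", dyf, self._cols, optimize=True).astype(
            np.float32
        )
        self.db += dyf.sum(axis=(0, 2)).astype(np.float32)
        dcols = np.matmul(self.w.T, dyf)
        return _col2im(
            dcols, self._xshape, self.k, self.stride, self.pad, self._ho, self._wo
        )


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat = xhat.astype(np.float32)
        self._inv = inv
        self._train = train
        return (self.gamma[None, :, None, None] * self._xhat
                + self.beta[None, :, None, None])

    def backward(self, dy):
        n, c, h, w = dy.shape
        m = n * h * w
        self.dgamma += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        if not self._train:
            return dxhat * self._inv[None, :, None, None]
        inv = self._inv[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv / m) * (m * dxhat - t1 - self._xhat * t2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = he_init(rng, (cout, cin), cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw += (dy.T @ self._x).astype(np.float32)
        self.db += dy.sum(axis=0).astype(np.float32)
        return dy @ self.w


class Upsample2x(Layer):
    """Nearest-neighbor 2x spatial upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SGD:
    """Plain momentum SGD over a flat parameter/gradient list."""

    def __init__(self, params: List[np.ndarray], grads: List[np.ndarray], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params, self.grad_refs = params, grads
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p) for p in params]

    def zero_grad(self):
        for g in self.grad_refs:
            g[...] = 0.0

    def step(self):
        for p, g, v in zip(self.params, self.grad_refs, self.velocity):
            upd = g + self.weight_decay * p
            v *= self.momentum
            v += upd
            p -= (self.lr * v).astype(p.dtype)
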