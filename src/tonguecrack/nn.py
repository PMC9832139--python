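"""Minimal CPU neural-network layers used by the two-stage crack network.

All tensors are channels-last ``(N, H, W, C)`` float arrays.  Convolutions
are stride-1, same-padded cross-correlations computed as im2col + a single
BLAS matrix product; the input gradient is recovered with a gemm followed by
a kernel-offset scatter-add (col2im), which avoids re-building patch
matrices on the backward pass.  Everything is deterministic: no threads, no
atomics, plain float arithmetic in a fixed order.

Layers cache what they need for the backward pass on ``forward`` and
accumulate parameter gradients on ``backward``; :class:`SGD` applies plain
stochastic-gradient updates.  ``dtype`` is configurable per layer so tests
can run gradient checks in float64 while training uses float32.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "SGD",
    "sigmoid",
]


def sigmoid(x):
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameters are (name, value, grad) triples."""

    def params(self):
        return []

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0

    def state_dict(self, prefix=""):
        state = {prefix + name: value for name, value, _ in self.params()}
        state.update(self.buffers(prefix))
        return state

    def buffers(self, prefix=""):
        return {}

    def load_state(self, state, prefix=""):
        for name, value, _ in self.params():
            value[...] = state[prefix + name]
        for name, value in self.buffers(prefix).items():
            value[...] = state[name]


class Conv2d(Layer):
    """Stride-1, same-padded 2-D convolution (cross-correlation).

    Weights have shape ``(k, k, c_in, c_out)``; odd kernel sizes only, so the
    output spatial size equals the input's.
    """

    def __init__(self, c_in, c_out, kernel, rng=None, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = (kernel - 1) // 2
        fan_in = kernel * kernel * c_in
        if rng is None:
            w = np.zeros((fan_in, c_out))
        else:
            # He initialisation: suits the ReLU blocks this layer sits in.
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = np.asarray(w, dtype=dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def _im2col(self, xp, h, w):
        # xp: padded input (N, h+2p, w+2p, C) -> (N*h*w, k*k*C)
        v = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (N, h, w, C, k, k) -> (N, h, w, k, k, C); the trailing (k, C) runs
        # are contiguous in memory which keeps the copy cheap.
        cols = v.transpose(0, 1, 2, 4, 5, 3).reshape(-1, self.k * self.k * self.c_in)
        return np.ascontiguousarray(cols)

    def forward(self, x, keep_cache=True):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols = self._im2col(xp, h, w)
        y = cols @ self.w
        y += self.b
        if keep_cache:
            self._cols = cols
            self._xshape = (n, h, w)
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy, need_dx=True):
        n, h, w = self._xshape
        dy_mat = dy.reshape(-1, self.c_out)
        # gradients are (re)bound, not accumulated: one backward per step
        self.gw = self._cols.T @ dy_mat
        self.gb = dy_mat.sum(axis=0)
        self._cols = None
        if not need_dx:
            return None
        gcols = dy_mat @ self.w.T
        gcols = gcols.reshape(n, h, w, self.k, self.k, self.c_in)
        p = self.pad
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=dy.dtype)
        for ky in range(self.k):
            for kx in range(self.k):
                gxp[:, ky : ky + h, kx : kx + w, :] += gcols[:, :, :, ky, kx, :]
        return gxp[:, p : p + h, p : p + w, :] if p else gxp


class BatchNorm2d(Layer):
    """Batch normalisation over (N, H, W) with running statistics.

    Training mode normalises with batch statistics and updates the running
    mean/variance with momentum 0.9 (``running = 0.9 running + 0.1 batch``);
    evaluation mode uses the running statistics.
    """

    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def buffers(self, prefix=""):
        return {
            prefix + "running_mean": self.running_mean,
            prefix + "running_var": self.running_var,
        }

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(x.dtype), train)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv, train = self._cache
        self._cache = None
        axes = (0, 1, 2)
        self.ggamma = (dy * xhat).sum(axis=axes)
        self.gbeta = dy.sum(axis=axes)
        if not train:
            return dy * self.gamma * inv
        m = float(np.prod(dy.shape[:3]))
        dxhat = dy * self.gamma
        return (
            inv
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2, stride-2 max pooling; odd trailing rows/columns are dropped."""

    def forward(self, x):
        n, h, w, c = x.shape
        hh, ww = h // 2, w // 2
        self._xshape = x.shape
        xc = x[:, : 2 * hh, : 2 * ww, :]
        v = xc.reshape(n, hh, 2, ww, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, hh, ww, c, 4
        )
        self._idx = v.argmax(axis=-1)
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._xshape
        hh, ww = h // 2, w // 2
        dv = np.zeros((n, hh, ww, c, 4), dtype=dy.dtype)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, : 2 * hh, : 2 * ww, :] = (
            dv.reshape(n, hh, ww, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
                n, 2 * hh, 2 * ww, c
            )
        )
        self._idx = None
        return dx


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float32):
        if rng is None:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, math.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.w = np.asarray(w, dtype=dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.gw = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class SGD:
    """Plain stochastic gradient descent (no momentum, no weight decay)."""

    def __init__(self, layers, lr):
        self.layers = [l for l in layers if l.params()]
        self.lr = lr

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def step(self):
        for layer in self.layers:
            for _, value, grad in layer.params():
                np.subtract(
                    value,
                    np.multiply(grad, self.lr, dtype=value.dtype),
                    out=value,
                )
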