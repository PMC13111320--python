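"""Minimal CPU neural-network framework (numpy, manual backprop).

Implements exactly the pieces the phenology classifier needs: standard,
pointwise and depthwise 2-D convolutions with 'same' padding (im2col based),
batch normalization, ReLU6, inverted-residual blocks, global average pooling,
dense layers, dropout, and an Adam optimizer. Tensors are laid out
``(batch, channels, height, width)``; every layer exposes ``forward`` /
``backward`` and collects ``(param, grad)`` pairs for the optimizer.

The implementation favours clarity and small-input efficiency over
generality: inputs here are 26x3 pseudo-images, so all matmuls are tiny and
the framework stays overhead-bound rather than FLOP-bound.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU6",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Sequential",
    "InvertedResidual",
    "Adam",
]


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Standard convolution, 'same' padding, optional row/column strides."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride=(1, 1), rng=None, bias=False):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None
        self.k = kernel
        self.stride = stride

    def params(self):
        out = [(self.w, self.dw)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        sh, sw = self.stride
        if self.k == 1 and self.stride == (1, 1):
            self._x = x
            out = np.einsum("nchw,oc->nohw", x, self.w[:, :, 0, 0], optimize=True)
        else:
            ph, pw = _same_pad(h, self.k, sh), _same_pad(w, self.k, sw)
            xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
            win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, ::sh, ::sw]
            self._win = win  # (n, c, oh, ow, k, k)
            self._shape = (x.shape, ph, pw, win.shape[2], win.shape[3])
            out = np.einsum("nchwab,ocab->nohw", win, self.w, optimize=True)
        if self.b is not None:
            out += self.b[None, :, None, None]
        return out

    def backward(self, grad):
        if self.b is not None:
            self.db[...] = grad.sum(axis=(0, 2, 3))
        if self.k == 1 and self.stride == (1, 1):
            self.dw[...] = np.einsum("nohw,nchw->oc", grad, self._x, optimize=True)[
                :, :, None, None
            ]
            return np.einsum("nohw,oc->nchw", grad, self.w[:, :, 0, 0], optimize=True)
        (xshape, ph, pw, oh, ow) = self._shape
        sh, sw = self.stride
        self.dw[...] = np.einsum("nohw,nchwab->ocab", grad, self._win, optimize=True)
        n, c, h, w = xshape
        dxp = np.zeros((n, c, h + sum(ph), w + sum(pw)), dtype=grad.dtype)
        # scatter-add per kernel tap
        dcol = np.einsum("nohw,ocab->nchwab", grad, self.w, optimize=True)
        for a in range(self.k):
            for b in range(self.k):
                dxp[:, :, a : a + oh * sh : sh, b : b + ow * sw : sw] += dcol[:, :, :, :, a, b]
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class DepthwiseConv2d(Layer):
    """Per-channel spatial convolution, 'same' padding."""

    def __init__(self, channels: int, kernel: int, stride=(1, 1), rng=None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / (kernel * kernel)), (channels, kernel, kernel)).astype(np.float32)
        self.dw = np.zeros_like(self.w)
        self.k = kernel
        self.stride = stride

    def params(self):
        return [(self.w, self.dw)]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        sh, sw = self.stride
        ph, pw = _same_pad(h, self.k, sh), _same_pad(w, self.k, sw)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        oh = -(-h // sh)
        ow = -(-w // sw)
        self._xp = xp
        self._shape = (x.shape, ph, pw, oh, ow)
        # accumulate one kernel tap at a time; all slices are plain views
        out = np.zeros((n, c, oh, ow), dtype=xp.dtype)
        for a in range(self.k):
            for b in range(self.k):
                out += xp[:, :, a : a + oh * sh : sh, b : b + ow * sw : sw] * (
                    self.w[None, :, a, b, None, None]
                )
        return out

    def backward(self, grad):
        (xshape, ph, pw, oh, ow) = self._shape
        sh, sw = self.stride
        n, c, h, w = xshape
        dxp = np.zeros((n, c, h + sum(ph), w + sum(pw)), dtype=grad.dtype)
        for a in range(self.k):
            for b in range(self.k):
                sl = np.s_[:, :, a : a + oh * sh : sh, b : b + ow * sw : sw]
                self.dw[:, a, b] = (grad * self._xp[sl]).sum(axis=(0, 2, 3))
                dxp[sl] += grad * self.w[None, :, a, b, None, None]
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros(channels, dtype=np.float32)
        self.dbeta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._inv[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        self.dgamma[...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * self._inv[None, :, None, None]
        mean_dy = grad.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dy_xhat = (grad * self._xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (grad - mean_dy - self._xhat * mean_dy_xhat)


class ReLU6(Layer):
    def forward(self, x, train=False):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / self._hw


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng=None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng=None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class InvertedResidual(Layer):
    """Expansion -> depthwise -> linear projection, with identity skip when
    the shapes allow (stride 1 and equal channel counts)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride=(1, 1), expansion=4, rng=None):
        mid = max(in_ch * expansion, 4)
        self.body = Sequential(
            Conv2d(in_ch, mid, 1, rng=rng),
            BatchNorm2d(mid),
            ReLU6(),
            DepthwiseConv2d(mid, kernel, stride=stride, rng=rng),
            BatchNorm2d(mid),
            ReLU6(),
            Conv2d(mid, out_ch, 1, rng=rng),
            BatchNorm2d(out_ch),
        )
        self.use_res = stride == (1, 1) and in_ch == out_ch

    def params(self):
        return self.body.params()

    def forward(self, x, train=False):
        out = self.body.forward(x, train)
        return out + x if self.use_res else out

    def backward(self, grad):
        dx = self.body.backward(grad)
        return dx + grad if self.use_res else dx


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
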