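"""Minimal CPU neural-network engine (numpy, reverse-mode by hand).

Just enough machinery for the concatenated classifier: 2-D convolution
(im2col), batch normalization, max/global-average pooling, dense
layers, bottleneck residual blocks, and an Adam optimizer. Layouts are
NCHW; parameters are float64 so seeded training is bitwise-reproducible
on CPU. Every ``backward`` consumes the cache left by the immediately
preceding ``forward`` — layers are therefore not reentrant, which is
fine for plain minibatch training.
"""
from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def _cols(self, xp: np.ndarray) -> tuple[np.ndarray, int, int]:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return cols, ho, wo

    def forward(self, x, train):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if xp.shape[2] < self.k or xp.shape[3] < self.k:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} too small for kernel {self.k} "
                f"with padding {p}"
            )
        cols, ho, wo = self._cols(xp)
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        y = cols @ self.W.value.T + self.b.value
        return y.reshape(x.shape[0], ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, xpshape, ho, wo = self._cache
        n = xshape[0]
        dyc = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.W.grad += dyc.T @ cols
        self.b.grad += dyc.sum(axis=0)
        dcols = (dyc @ self.W.value).reshape(n, ho, wo, self.cin, self.k, self.k)
        dxp = np.zeros(xpshape)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        p = self.pad
        return dxp[:, :, p : p + xshape[2], p : p + xshape[3]] if p else dxp


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        if not train:
            return dy * g * inv_std[:, None, None]
        count = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))[:, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))[:, None, None]
        return inv_std[:, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        self._argmax = flat.argmax(axis=4)
        self._shapes = (x.shape, xp.shape, ho, wo)
        return flat.max(axis=4)

    def backward(self, dy):
        xshape, xpshape, ho, wo = self._shapes
        n, c = xshape[0], xshape[1]
        k, s, p = self.k, self.stride, self.pad
        rows = (np.arange(ho) * s)[None, None, :, None] + self._argmax // k
        cols = (np.arange(wo) * s)[None, None, None, :] + self._argmax % k
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        dxp = np.zeros(xpshape)
        np.add.at(dxp, (ni, ci, rows, cols), dy)
        return dxp[:, :, p : p + xshape[2], p : p + xshape[3]] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
        self.b = Param(np.zeros(dout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Bottleneck(Layer):
    """1x1 -> 3x3 -> 1x1 residual block with 4x channel expansion.

    The identity (or 1x1-projection) shortcut is summed onto the main
    path before the final ReLU.
    """

    def __init__(self, cin: int, cmid: int, stride: int, rng: np.random.Generator):
        cout = 4 * cmid
        self.main = Sequential([
            Conv2D(cin, cmid, 1, 1, 0, rng), BatchNorm2D(cmid), ReLU(),
            Conv2D(cmid, cmid, 3, stride, 1, rng), BatchNorm2D(cmid), ReLU(),
            Conv2D(cmid, cout, 1, 1, 0, rng), BatchNorm2D(cout),
        ])
        self.proj: Sequential | None = None
        if stride != 1 or cin != cout:
            self.proj = Sequential([Conv2D(cin, cout, 1, stride, 0, rng), BatchNorm2D(cout)])

    def params(self):
        ps = self.main.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train):
        main = self.main.forward(x, train)
        short = self.proj.forward(x, train) if self.proj is not None else x
        out = main + short
        self._mask = out > 0
        return out * self._mask

    def backward(self, dy):
        d = dy * self._mask
        dx = self.main.backward(d)
        dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
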