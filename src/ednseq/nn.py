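"""Minimal feed-forward neural-network engine on NumPy.

Implements exactly the layer types the hybrid classifier needs —
same-padded 1-d/2-d convolutions, ReLU, length-2 max pooling, adaptive
max pooling to a fixed length, axis-max reduction, dropout and dense
layers — each with an explicit backward pass, plus the Adam optimizer.
All arrays are double precision; gradients are exact (no numerical
differentiation).  Layers carry no batch-coupled state, so a sample's
output is independent of its batch peers.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1d",
    "Conv2d",
    "Dense",
    "ReLU",
    "MaxPool1d",
    "AdaptiveMaxPool1d",
    "MaxOverAxis",
    "Dropout",
    "Flatten",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


class Layer:
    """Base layer: optional parameters, cached forward state, backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """Same-padded 1-d convolution over (batch, channels, length)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("same padding requires an odd kernel size")
        self.cin, self.cout, self.kw = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size
        self.params["W"] = _kaiming_uniform(rng, (out_channels, fan_in), fan_in)
        self.params["b"] = _kaiming_uniform(rng, (out_channels,), fan_in)

    def forward(self, x, *, train=False, rng=None):
        B, C, L = x.shape
        p = self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.kw, axis=2)  # (B, C, L, kw)
        cols = win.transpose(0, 2, 1, 3).reshape(B, L, C * self.kw)
        self._cols, self._in_shape = cols, (B, C, L)
        out = cols @ self.params["W"].T + self.params["b"]
        return out.transpose(0, 2, 1)  # (B, O, L)

    def backward(self, dout):
        B, C, L = self._in_shape
        d = dout.transpose(0, 2, 1)  # (B, L, O)
        flat_d = d.reshape(B * L, self.cout)
        flat_c = self._cols.reshape(B * L, C * self.kw)
        self.grads["W"] = flat_d.T @ flat_c
        self.grads["b"] = flat_d.sum(axis=0)
        dcols = (d @ self.params["W"]).reshape(B, L, C, self.kw)
        p = self.kw // 2
        dxp = np.zeros((B, C, L + 2 * p))
        for j in range(self.kw):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + L]


class Conv2d(Layer):
    """Same-padded 2-d convolution over (batch, channels, height, width)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same padding requires odd kernel extents")
        self.cin, self.cout, self.kh, self.kw = in_channels, out_channels, kh, kw
        fan_in = in_channels * kh * kw
        self.params["W"] = _kaiming_uniform(rng, (out_channels, fan_in), fan_in)
        self.params["b"] = _kaiming_uniform(rng, (out_channels,), fan_in)

    def forward(self, x, *, train=False, rng=None):
        B, C, H, Wd = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))  # (B, C, H, W, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * Wd, C * self.kh * self.kw)
        self._cols, self._in_shape = cols, (B, C, H, Wd)
        out = cols @ self.params["W"].T + self.params["b"]  # (B, H*W, O)
        return out.reshape(B, H, Wd, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        B, C, H, Wd = self._in_shape
        d = dout.transpose(0, 2, 3, 1).reshape(B * H * Wd, self.cout)
        flat_c = self._cols.reshape(B * H * Wd, -1)
        self.grads["W"] = d.T @ flat_c
        self.grads["b"] = d.sum(axis=0)
        dcols = (d @ self.params["W"]).reshape(B, H, Wd, C, self.kh, self.kw)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((B, C, H + 2 * ph, Wd + 2 * pw))
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + H, j : j + Wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, ph : ph + H, pw : pw + Wd]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.fin, self.fout = in_features, out_features
        self.params["W"] = _kaiming_uniform(rng, (out_features, in_features), in_features)
        self.params["b"] = _kaiming_uniform(rng, (out_features,), in_features)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling with window 2 (floor on odd lengths)."""

    def forward(self, x, *, train=False, rng=None):
        B, C, L = x.shape
        L2 = L // 2
        xt = x[:, :, : 2 * L2].reshape(B, C, L2, 2)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = (B, C, L)
        return xt.max(axis=3)

    def backward(self, dout):
        B, C, L = self._in_shape
        L2 = L // 2
        dx = np.zeros((B, C, L2, 2))
        np.put_along_axis(dx, self._argmax[..., None], dout[..., None], axis=3)
        out = np.zeros((B, C, L))
        out[:, :, : 2 * L2] = dx.reshape(B, C, 2 * L2)
        return out


class AdaptiveMaxPool1d(Layer):
    """Max pooling to a fixed output length regardless of input length.

    Output bin i covers input positions [floor(i*L/T), ceil((i+1)*L/T)),
    so any L >= 1 is accepted (bins overlap when L < T).
    """

    def __init__(self, target: int):
        super().__init__()
        self.target = target

    def forward(self, x, *, train=False, rng=None):
        B, C, L = x.shape
        if L < 1:
            raise ValueError("adaptive pooling needs at least one position")
        T = self.target
        out = np.empty((B, C, T))
        argmax = np.empty((B, C, T), dtype=np.int64)
        for i in range(T):
            s, e = (i * L) // T, -(-(i + 1) * L // T)
            seg = x[:, :, s:e]
            idx = seg.argmax(axis=2)
            argmax[:, :, i] = idx + s
            out[:, :, i] = np.take_along_axis(seg, idx[..., None], axis=2)[..., 0]
        self._argmax, self._in_shape = argmax, (B, C, L)
        return out

    def backward(self, dout):
        B, C, L = self._in_shape
        dx = np.zeros((B, C, L))
        bi, ci = np.ix_(np.arange(B), np.arange(C))
        for i in range(self.target):
            np.add.at(dx, (bi, ci, self._argmax[:, :, i]), dout[:, :, i])
        return dx


class MaxOverAxis(Layer):
    """Reduce one axis by maximum (used to collapse the scale axis)."""

    def __init__(self, axis: int = 2):
        super().__init__()
        self.axis = axis

    def forward(self, x, *, train=False, rng=None):
        self._argmax = np.expand_dims(x.argmax(axis=self.axis), self.axis)
        self._in_shape = x.shape
        return x.max(axis=self.axis)

    def backward(self, dout):
        dx = np.zeros(self._in_shape)
        np.put_along_axis(dx, self._argmax, np.expand_dims(dout, self.axis), axis=self.axis)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an RNG")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, *, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def iter_params(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{li}.{name}", layer

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)


class Adam:
    """Adam optimizer over a {key: (layer, param name)} mapping."""

    def __init__(self, modules: dict[str, Layer], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.modules = modules
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: {n: np.zeros_like(p) for n, p in mod.params.items()} for k, mod in modules.items()}
        self.v = {k: {n: np.zeros_like(p) for n, p in mod.params.items()} for k, mod in modules.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, mod in self.modules.items():
            for name, p in mod.params.items():
                g = mod.grads[name]
                m = self.m[key][name]
                v = self.v[key][name]
                m *= self.b1
                m += (1.0 - self.b1) * g
                v *= self.b2
                v += (1.0 - self.b2) * np.square(g)
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits ``z`` against labels ``y``.

    Returns (loss, dloss/dz); the gradient is sigmoid(z) - y over n,
    which is numerically stable for large |z|.
    """
    n = z.size
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    return loss, (sigmoid(z) - y) / n
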