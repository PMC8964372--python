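"""Deterministic CPU neural-network backend.

A small, fully vectorized numpy implementation of the layers the multimodal
classifier needs: 3x3 same-padding convolutions (im2col), 2x2 max pooling,
batch normalization, dense layers, inverted dropout, a sigmoid output with
binary cross-entropy loss, and the Adam optimizer.  All randomness flows
from a single ``numpy.random.Generator``, so training is bit-reproducible
given a seed.

Shapes follow the NCHW convention for images and (N, D) for dense inputs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2",
    "BatchNorm",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_loss",
]

_EPS = 1e-5


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Layer:
    """Base layer; subclasses fill ``params``/``grads`` dicts by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, optional ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 relu: bool = True):
        super().__init__()
        k = 3
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.params["W"] = rng.normal(0.0, scale, size=(out_channels, fan_in))
        self.params["b"] = np.zeros(out_channels)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.relu = relu

    def forward(self, x, training):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        out = cols @ self.params["W"].T + self.params["b"]
        out = out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        self._cols = cols
        self._shape = (n, c, h, w)
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        if self.relu:
            dout = dout * self._mask
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.grads["W"] = dmat.T @ self._cols
        self.grads["b"] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"]  # (N*H*W, C*9)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        patches = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = patches.reshape(n, c, h2, w2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, c, h2, w2, 4))
        idx = np.indices((n, c, h2, w2))
        dflat[idx[0], idx[1], idx[2], idx[3], self._argmax] = dout
        dxc = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxc = dxc.reshape(n, c, 2 * h2, 2 * w2)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = dxc
        return dx


class BatchNorm(Layer):
    """Batch normalization over channels (4-D input) or features (2-D input).

    Running statistics (momentum 0.9) are used at inference time.
    """

    def __init__(self, num_features: int, momentum: float = 0.9):
        super().__init__()
        self.params["gamma"] = np.ones(num_features)
        self.params["beta"] = np.zeros(num_features)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.num_features = num_features

    def _axes(self, x):
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _reshape(self, v, ndim):
        return v.reshape(1, -1, 1, 1) if ndim == 4 else v.reshape(1, -1)

    def forward(self, x, training):
        axes = self._axes(x)
        nd = x.ndim
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + _EPS)
        xhat = (x - self._reshape(mean, nd)) / self._reshape(std, nd)
        self._xhat, self._std, self._axes_cache = xhat, std, axes
        return self._reshape(self.params["gamma"], nd) * xhat + self._reshape(
            self.params["beta"], nd
        )

    def backward(self, dout):
        axes = self._axes_cache
        nd = dout.ndim
        m = np.prod([dout.shape[a] for a in axes])
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self._reshape(self.params["gamma"], nd)
        dxhat = dout * g
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / self._reshape(std, nd)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 relu: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, scale, size=(in_features, out_features))
        self.params["b"] = np.zeros(out_features)
        self.relu = relu
        self.in_features = in_features

    def forward(self, x, training):
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got {x.shape[1]}"
            )
        self._x = x
        out = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


class Adam:
    """Adam optimizer over (layer, param-name) handles."""

    def __init__(self, handles, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.handles = list(handles)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[n]) for layer, n in self.handles]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in self.handles]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
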