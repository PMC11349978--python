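"""Compact numpy neural-network layers for the dual-branch CNN.

Implements exactly what the dual CNN needs — stride-1 same-padded
convolution (im2col), ReLU, 2x2 stride-2 max pooling, global average
pooling, dense layers and a softmax cross-entropy head — with explicit
backward passes and seeded SGD-with-momentum.  All parameters are float32;
every source of randomness flows through one numpy Generator so training
is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "softmax",
    "cross_entropy",
    "SGD",
]

DTYPE = np.float32


class Layer:
    params: tuple = ()

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 convolution with same padding (odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        # He-normal initialisation for ReLU nonlinearities
        self.W = (rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.params = ("W", "b")

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=DTYPE)
        out = cols @ self.W.T + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = grad.shape
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels))
        self.dW = gmat.T @ self._cols
        self.db = gmat.sum(axis=0)
        dcols = (gmat @ self.W).reshape(n, h, w, self.in_channels, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, self.in_channels, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        del self._cols
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2 (odd trailing rows/cols dropped)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h < 2 or w < 2:
            raise ValueError(f"feature map {h}x{w} too small for 2x2 pooling")
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        out = xc.max(axis=(3, 5))
        if train:
            self._xc = xc
            self._out = out
            self._in_shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._xc == self._out[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w), dtype=DTYPE)
        dxc = mask * grad[:, :, :, None, :, None]
        dx[:, :, : 2 * h2, : 2 * w2] = dxc.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)).astype(DTYPE) / (h * w)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((out_features, in_features)) * np.sqrt(2.0 / in_features)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.params = ("W", "b")

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``.

    The mask sequence is drawn from the generator handed in at
    construction, so training remains bit-reproducible for a fixed seed.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean cross-entropy; ``targets`` are integer class indices."""
    eps = np.finfo(probs.dtype).tiny
    return float(-np.log(probs[np.arange(len(targets)), targets] + eps).mean())


class SGD:
    """SGD with momentum and L2 weight decay over a list of layers."""

    def __init__(self, layers, lr: float = 0.01, momentum: float = 0.9, weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {
            (id(l), p): np.zeros_like(getattr(l, p)) for l in self.layers for p in l.params
        }

    def step(self):
        for layer in self.layers:
            for p in layer.params:
                g = getattr(layer, "d" + p).astype(DTYPE)
                if self.weight_decay and p == "W":
                    g = g + DTYPE(self.weight_decay) * getattr(layer, p)
                v = self.velocity[(id(layer), p)]
                v *= self.momentum
                v -= self.lr * g
                getattr(layer, p).__iadd__(v)
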