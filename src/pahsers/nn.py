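"""Minimal 1D convolutional network engine in numpy.

Implements exactly the pieces the spectral models need — same-padded 1D
convolutions, ReLU, max pooling, dense layers, inverted dropout, Adam, and
the two losses (multilabel binary cross-entropy with logits, mean squared
error) — with hand-written backpropagation. Shapes follow the (batch,
channels, length) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "bce_with_logits",
    "mse_loss",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: parameters and their gradients live in parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1D convolution, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError(f"kernel width must be odd, got {kernel}")
        fan_in = in_ch * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_ch * kernel, out_ch))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        B, C, L = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (B, C, L, k) windows -> (B*L, C*k) columns
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(B * L, C * self.kernel)
        self._cols = cols
        self._shape = (B, C, L)
        y = cols @ self.W + self.b
        return y.reshape(B, L, self.out_ch).transpose(0, 2, 1)

    def backward(self, dy):
        B, C, L = self._shape
        k, p = self.kernel, self.kernel // 2
        dyt = dy.transpose(0, 2, 1).reshape(B * L, self.out_ch)
        self.dW[...] = self._cols.T @ dyt
        self.db[...] = dyt.sum(axis=0)
        dcols = (dyt @ self.W.T).reshape(B, L, C, k)
        dxp = np.zeros((B, C, L + 2 * p))
        for j in range(k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + L]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, width: int):
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width

    def forward(self, x, train=False, rng=None):
        B, C, L = x.shape
        w = self.width
        Lp = L // w
        xt = x[:, :, : Lp * w].reshape(B, C, Lp, w)
        self._arg = xt.argmax(axis=3)
        self._shape = (B, C, L)
        return xt.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        w = self.width
        Lp = L // w
        dx = np.zeros((B, C, Lp, w))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        out = np.zeros((B, C, L))
        out[:, :, : Lp * w] = dx.reshape(B, C, Lp * w)
        return out


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """A plain sequential stack."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean multilabel binary cross-entropy and its gradient w.r.t. logits."""
    n = logits.size
    loss = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    grad = (sigmoid(logits) - y) / n
    return float(loss.mean()), grad


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. predictions."""
    diff = pred - y
    return float((diff**2).mean()), 2.0 * diff / pred.size
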