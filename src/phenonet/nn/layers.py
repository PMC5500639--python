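"""Layer implementations with analytic forward/backward passes.

All image tensors are NHWC float32.  Convolutions are same-padded with
stride 1 (odd kernels), so an n x m x c input maps to n x m x k; max
pooling uses same padding with an arbitrary stride, mapping n to ceil(n/s).
Backward passes accumulate parameter gradients in-place (`dW`, `db`) and
return the gradient with respect to the layer input.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError, ShapeError


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "none":
        return z
    raise ConfigurationError(f"unknown activation {kind!r}")


def _activation_grad(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed in terms of the cached activation a = f(z)
    if kind == "tanh":
        return 1.0 - a * a
    if kind == "relu":
        return (a > 0).astype(a.dtype)
    return np.ones_like(a)


def xavier_init(
    shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator
) -> np.ndarray:
    """Glorot uniform: entries in +-sqrt(6 / (fan_in + fan_out))."""
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    """Base layer; parameterless layers leave ``params`` empty."""

    trainable: bool = False

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def zero_grads(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    trainable = True

    def __init__(
        self,
        kernel: tuple[int, int],
        in_channels: int,
        filters: int,
        activation: str,
        rng: np.random.Generator,
    ):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError(f"convolution kernels must be odd-sized, got {kernel}")
        self.kh, self.kw = kh, kw
        self.cin, self.filters = in_channels, filters
        self.activation = activation
        fan_in = kh * kw * in_channels
        fan_out = kh * kw * filters
        self.W = xavier_init((kh, kw, in_channels, filters), fan_in, fan_out, rng)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training, rng=None):
        n, h, w, c = x.shape
        if c != self.cin:
            raise ShapeError(f"conv expected {self.cin} input channels, got {c}")
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1).astype(np.float32)
        z = cols @ self.W.reshape(-1, self.filters) + self.b
        a = _activate(z, self.activation)
        self._cols = cols
        self._in_shape = x.shape
        self._a = a
        return a.reshape(n, h, w, self.filters)

    def backward(self, dout):
        n, h, w, _ = self._in_shape
        dz = (dout.reshape(-1, self.filters) * _activation_grad(self._a, self.activation)).astype(
            np.float32
        )
        self.dW += (self._cols.T @ dz).reshape(self.W.shape)
        self.db += dz.sum(axis=0)
        ph, pw = self.kh // 2, self.kw // 2
        dzp = np.pad(dz.reshape(n, h, w, self.filters), ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = sliding_window_view(dzp, (self.kh, self.kw), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        w_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.cin)
        dx = (cols @ w_flip).reshape(n, h, w, self.cin)
        self._cols = self._a = None
        return dx


class MaxPool2D(Layer):
    def __init__(self, kernel: tuple[int, int], stride: int):
        self.kh, self.kw = kernel
        self.stride = stride
        if stride < 1:
            raise ConfigurationError("pool stride must be >= 1")

    @staticmethod
    def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
        out = math.ceil(size / s)
        total = max((out - 1) * s + k - size, 0)
        return out, total // 2, total - total // 2

    def forward(self, x, training, rng=None):
        n, h, w, c = x.shape
        s = self.stride
        oh, pt, pb = self._same_pad(h, self.kh, s)
        ow, pl, pr = self._same_pad(w, self.kw, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))[:, ::s, ::s]
        flat = win.reshape(n, oh, ow, c, self.kh * self.kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx, pt, pl, oh, ow)
        return out.astype(np.float32)

    def backward(self, dout):
        (in_shape, idx, pt, pl, oh, ow) = self._cache
        n, h, w, c = in_shape
        s = self.stride
        rows = (np.arange(oh) * s)[None, :, None, None] + idx // self.kw - pt
        cols = (np.arange(ow) * s)[None, None, :, None] + idx % self.kw - pl
        dx = np.zeros(in_shape, dtype=np.float32)
        n_idx = np.arange(n)[:, None, None, None]
        c_idx = np.arange(c)[None, None, None, :]
        np.add.at(dx, (n_idx, rows, cols, c_idx), dout)
        self._cache = None
        return dx


class Dense(Layer):
    """Fully connected layer; flattens any input volume."""

    trainable = True

    def __init__(self, in_dim: int, units: int, activation: str, rng: np.random.Generator):
        if units < 1:
            raise ConfigurationError("fully connected layer needs units >= 1")
        self.in_dim, self.units = in_dim, units
        self.activation = activation
        self.W = xavier_init((in_dim, units), in_dim, units, rng)
        self.b = np.zeros(units, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training, rng=None):
        n = x.shape[0]
        xf = x.reshape(n, -1).astype(np.float32)
        if xf.shape[1] != self.in_dim:
            raise ShapeError(
                f"fully connected layer expected {self.in_dim} inputs, got {xf.shape[1]}"
            )
        z = xf @ self.W + self.b
        a = _activate(z, self.activation)
        self._xf = xf
        self._a = a
        self._in_shape = x.shape
        return a

    def backward(self, dout):
        dz = (dout * _activation_grad(self._a, self.activation)).astype(np.float32)
        self.dW += self._xf.T @ dz
        self.db += dz.sum(axis=0)
        dx = (dz @ self.W.T).reshape(self._in_shape)
        self._xf = self._a = None
        return dx


class Dropout(Layer):
    """Inverted dropout: train-time scaling by 1/(1-p); eval is a no-op."""

    def __init__(self, drop_prob: float):
        if not 0.0 <= drop_prob < 1.0:
            raise ConfigurationError(f"drop probability must be in [0, 1), got {drop_prob}")
        self.p = drop_prob

    def forward(self, x, training, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ConfigurationError("dropout in training mode needs a random generator")
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask
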