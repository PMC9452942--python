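"""Minimal numpy neural-network layers with explicit backpropagation.

Every layer caches what its backward pass needs during ``forward`` and
exposes ``params()`` / ``grads()`` pairs for the optimizer.  All arithmetic
is float64 so analytic gradients can be validated against central finite
differences to tight tolerances.  Array layout is channels-last:
``(N, H, W, C)`` for feature maps, ``(N, D)`` for vectors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import SpecViolationError

__all__ = ["Layer", "Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "sigmoid"]


def sigmoid(x):
    """Logistic squashing ``1 / (1 + exp(-x))``, increasing onto (0, 1)."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Valid (no padding) stride-1 cross-correlation plus bias.

    Weights have shape ``(kh, kw, c_in, c_out)``.
    """

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = kh * kw * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._windows: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        kh, kw, c_in, _ = self.w.shape
        if x.ndim != 4 or x.shape[3] != c_in or x.shape[1] < kh or x.shape[2] < kw:
            raise SpecViolationError(
                f"conv input {x.shape} incompatible with kernel {self.w.shape}"
            )
        # (N, Ho, Wo, C_in, kh, kw)
        windows = sliding_window_view(x, (kh, kw), axis=(1, 2))
        self._windows = windows
        self._x_shape = x.shape
        return np.einsum("nhwcij,ijco->nhwo", windows, self.w, optimize=True) + self.b

    def backward(self, g):
        kh, kw, _, _ = self.w.shape
        self.dw[...] = np.einsum("nhwcij,nhwo->ijco", self._windows, g, optimize=True)
        self.db[...] = g.sum(axis=(0, 1, 2))
        dx = np.zeros(self._x_shape)
        n, ho, wo, _ = g.shape
        for i in range(kh):
            for j in range(kw):
                dx[:, i : i + ho, j : j + wo, :] += np.einsum(
                    "nhwo,co->nhwc", g, self.w[i, j], optimize=True
                )
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class MaxPool2(Layer):
    """2x2 non-overlapping max pooling; spatial dims must be even."""

    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise SpecViolationError(f"pool input {x.shape} has odd spatial size")
        tiles = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._argmax = np.argmax(tiles, axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(tiles, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, h, w, c = self._x_shape
        dtiles = np.zeros((n, h // 2, w // 2, c, 4))
        np.put_along_axis(dtiles, self._argmax[..., None], g[..., None], axis=-1)
        return (
            dtiles.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class Flatten(Layer):
    def forward(self, x):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._x_shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        if x.ndim != 2 or x.shape[1] != self.w.shape[0]:
            raise SpecViolationError(
                f"dense input {x.shape} incompatible with weight {self.w.shape}"
            )
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.w.T
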