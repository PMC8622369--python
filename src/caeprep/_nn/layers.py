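"""Minimal numpy layers for the small convolutional networks used here.

All tensors are NHWC float32.  Convolution is implemented by im2col + one
matmul; the transposed convolution is implemented exactly as the adjoint of
the corresponding convolution, which guarantees that a stride-2 deconv
inverts the shape arithmetic of the matching stride-2 conv.

Everything is deterministic: weights are drawn from a caller-supplied
``numpy.random.Generator`` and no threading or atomics are involved.
"""

from __future__ import annotations

import numpy as np


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    """Strided view (B, ho, wo, kh, kw, C) over the padded input."""
    b, _, _, c = xp.shape
    s0, s1, s2, s3 = xp.strides
    shape = (b, ho, wo, kh, kw, c)
    strides = (s0, s1 * stride, s2 * stride, s1, s2, s3)
    return np.lib.stride_tricks.as_strided(xp, shape, strides)


def conv_out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class Layer:
    """Base layer: parameters, gradients and a forward/backward pair."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, c_in, c_out, kernel, stride, pad, rng: np.random.Generator):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = kernel * kernel * c_in
        # He initialisation (fan-in scaled), standard for ReLU nets
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (kernel, kernel, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = conv_out_size(x.shape[1], k, s, p)
        wo = conv_out_size(x.shape[2], k, s, p)
        cols = _im2col(xp, k, k, s, ho, wo).reshape(-1, k * k * x.shape[3])
        cols = np.ascontiguousarray(cols)
        y = cols @ self.w.reshape(-1, self.w.shape[-1]) + self.b
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(x.shape[0], ho, wo, -1)

    def backward(self, dout):
        cols, x_shape, ho, wo = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        b, h, w, c_in = x_shape
        c_out = self.w.shape[-1]
        dflat = dout.reshape(-1, c_out)
        self.dw[...] = (cols.T @ dflat).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.w.reshape(-1, c_out).T).reshape(b, ho, wo, k, k, c_in)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c_in), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:h + p, p:w + p, :] if p else dxp


class ConvTranspose2D(Layer):
    """Transposed convolution: the exact adjoint of Conv2D(kernel, stride, pad).

    Maps (B, h, w, c_in) -> (B, (h-1)*stride + kernel - 2*pad, ..., c_out).
    """

    def __init__(self, c_in, c_out, kernel, stride, pad, rng: np.random.Generator):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = kernel * kernel * c_in
        # weight stored as the mirror conv's (k, k, c_out, c_in)
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (kernel, kernel, c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        b, h, w, c_in = x.shape
        c_out = self.w.shape[2]
        ho = (h - 1) * s + k - 2 * p
        wo = (w - 1) * s + k - 2 * p
        xflat = x.reshape(-1, c_in)
        # scatter-add of x through the mirror conv's weight
        dcols = (xflat @ self.w.reshape(-1, c_in).T).reshape(b, h, w, k, k, c_out)
        yp = np.zeros((b, ho + 2 * p, wo + 2 * p, c_out), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                yp[:, i:i + s * h:s, j:j + s * w:s, :] += dcols[:, :, :, i, j, :]
        y = yp[:, p:ho + p, p:wo + p, :] if p else yp
        self._cache = (x, ho, wo)
        return y + self.b

    def backward(self, dout):
        x, ho, wo = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        b, h, w, c_in = x.shape
        doutp = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0))) if p else dout
        cols = _im2col(doutp, k, k, s, h, w).reshape(-1, k * k * self.w.shape[2])
        cols = np.ascontiguousarray(cols)
        xflat = x.reshape(-1, c_in)
        self.dw[...] = (cols.T @ xflat).reshape(self.w.shape)
        self.db[...] = dout.sum(axis=(0, 1, 2))
        dx = cols @ self.w.reshape(-1, c_in)
        return dx.reshape(x.shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class Sigmoid(Layer):
    def forward(self, x):
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class GlobalAveragePool(Layer):
    """(B, H, W, C) -> (B, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        b, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), self._shape
        ).astype(dout.dtype)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s
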