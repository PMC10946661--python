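"""Minimal NumPy convolution-network primitives with manual backprop.

Layers cache what their backward pass needs on each forward call, so a
layer instance is used once per network forward.  All tensors are float32
``(N, C, H, W)`` for feature maps and ``(N, D)`` for dense features.
Gradients accumulate into ``Param.grad`` and are consumed by the Adam
optimizer in :mod:`grainpigment.nn.train`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "Linear",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "GlobalAvgPool",
    "concat_channels",
    "split_channels",
]


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of a padded 3x3 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class Conv2d:
    """3x3 (or 1x1) same convolution via im2col matmul."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        # He initialization for ReLU nets
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.kernel == 1:
            col = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        else:
            col = _im2col3(x)
        out = col @ self.W.value + self.b.value
        self._cache = (col, (n, c, h, w))
        return np.ascontiguousarray(
            out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, (n, c, h, w) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.W.grad += col.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        if self.kernel == 1:
            dx = dflat @ self.W.value.T
            return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))
        # dx = full correlation of dout with the spatially flipped kernel
        W = self.W.value.reshape(c, 3, 3, self.c_out)
        W_flip = W[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * 9, c)
        dcol = _im2col3(dout.reshape(n, self.c_out, h, w))
        dx = dcol @ W_flip
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class InstanceNorm:
    """Per-sample, per-channel normalization with affine parameters.

    Stateless across batches (no running statistics), so train and eval
    behavior are identical and training stays stable at high learning
    rates with tiny batch sizes.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        return (
            dxhat
            - dxhat.mean(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        ) * inv


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self):
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        x4 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x4 = x4.reshape(n, c, h // 2, w // 2, 4)
        idx = x4.argmax(axis=-1)
        self._cache = (idx, (n, c, h, w))
        return np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(d4, idx[..., None], dout[..., None], axis=-1)
        d4 = d4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(d4.reshape(n, c, h, w))


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        d = dout.reshape(n, c, h // 2, 2, w // 2, 2)
        return d.sum(axis=(3, 5))


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


def concat_channels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.concatenate([a, b], axis=1)


def split_channels(d: np.ndarray, c_a: int) -> tuple[np.ndarray, np.ndarray]:
    return d[:, :c_a], d[:, c_a:]
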