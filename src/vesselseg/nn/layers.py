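"""Layers for the NumPy conv-net engine.

Convolution runs as an im2col + GEMM; its backward pass scatters
gradients back with one strided slice-add per kernel offset, which keeps
everything inside BLAS / vectorized NumPy.  Activations and gradients
use the engine dtype (float32 by default; see ``core.set_dtype``).
"""

from __future__ import annotations

import functools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import core
from .core import Module, Parameter

def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(core.DTYPE)


class Conv2d(Module):
    """2-D convolution, NCHW, square kernel, symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(he_normal(rng, (out_channels, in_channels,
                                                kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=core.DTYPE)
        out = cols @ self.weight.data.reshape(self.out_channels, -1).T
        if self.bias is not None:
            out += self.bias.data
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols, ho, wo = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        gmat = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 1).reshape(-1, self.out_channels), dtype=core.DTYPE)
        self.weight.grad += (gmat.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=0)
        gcols = gmat @ self.weight.data.reshape(self.out_channels, -1)
        gc = gcols.reshape(n, ho, wo, c, k, k)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=core.DTYPE)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    gc[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._cache = None
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class ConvTranspose2d(Module):
    """Transposed convolution; output side = s*(i-1) + k - 2p."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(he_normal(rng, (in_channels, out_channels,
                                                kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._x = None

    def output_size(self, i: int) -> int:
        return self.stride * (i - 1) + self.kernel_size - 2 * self.padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, hi, wi = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = self.output_size(hi), self.output_size(wi)
        ypad = np.zeros((n, self.out_channels, ho + 2 * p, wo + 2 * p), dtype=core.DTYPE)
        for ki in range(k):
            for kj in range(k):
                contrib = np.tensordot(x, self.weight.data[:, :, ki, kj],
                                       axes=([1], [0]))  # (n, hi, wi, cout)
                ypad[:, :, ki:ki + s * hi:s, kj:kj + s * wi:s] += \
                    contrib.transpose(0, 3, 1, 2)
        y = ypad[:, :, p:p + ho, p:p + wo] if p else ypad
        if self.bias is not None:
            y += self.bias.data[:, None, None]
        self._x = x
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, hi, wi = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p))) if p else grad
        gx = np.zeros_like(x)
        for ki in range(k):
            for kj in range(k):
                sub = gp[:, :, ki:ki + s * hi:s, kj:kj + s * wi:s]  # (n,cout,hi,wi)
                gx += np.tensordot(sub, self.weight.data[:, :, ki, kj],
                                   axes=([1], [1])).transpose(0, 3, 1, 2)
                self.weight.grad[:, :, ki, kj] += np.tensordot(
                    x, sub, axes=([0, 2, 3], [0, 2, 3]))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        self._x = None
        return gx


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=core.DTYPE)
        self.running_var = np.ones(channels, dtype=core.DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(core.DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(core.DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        xhat = xhat.astype(core.DTYPE, copy=False)
        self._cache = (xhat, invstd.astype(core.DTYPE))
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.data[:, None, None]
        if not self.training:
            self._cache = None
            return gxhat * invstd[:, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        gx = invstd[:, None, None] * (gxhat - s1 / m - xhat * s2 / m)
        self._cache = None
        return gx.astype(core.DTYPE, copy=False)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(core.DTYPE, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, grad, 0.0).astype(core.DTYPE, copy=False)
        self._mask = None
        return g


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        self._y = y.astype(core.DTYPE)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._y * (1.0 - self._y)
        self._y = None
        return g


class PixelShuffle(Module):
    """Parameter-free periodic rearrangement (depth-to-space).

    ``out[c, y, x] = in[c*r*r + (y % r)*r + (x % r), y // r, x // r]``
    applied per batch item; exactly invertible.
    """

    def __init__(self, r: int):
        super().__init__()
        if r < 1:
            raise ValueError("subwindow factor r must be >= 1")
        self.r = r

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r = self.r
        if c % (r * r):
            raise ValueError(
                f"channel count {c} not divisible by r^2 = {r * r}")
        co = c // (r * r)
        out = x.reshape(n, co, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out.reshape(n, co, h * r, w * r))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, co, hr, wr = grad.shape
        r = self.r
        h, w = hr // r, wr // r
        g = grad.reshape(n, co, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(g.reshape(n, co * r * r, h, w))


@functools.lru_cache(maxsize=256)
def resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Corner-aligned 1-D bilinear resampling matrix (n_out x n_in).

    Each output sample is a convex combination of its two nearest source
    samples; first/last samples map exactly onto first/last.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("resize sizes must be positive")
    mat = np.zeros((n_out, n_in), dtype=np.float64)
    if n_out == 1:
        mat[0, 0] = 1.0
        return mat
    scale = (n_in - 1) / (n_out - 1)
    for o in range(n_out):
        src = o * scale
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        mat[o, i0] += 1.0 - t
        mat[o, i1] += t
    mat.setflags(write=False)
    return mat


class BilinearResize(Module):
    """Corner-aligned separable bilinear resize to a fixed target size."""

    def __init__(self, out_height: int, out_width: int):
        super().__init__()
        if out_height < 1 or out_width < 1:
            raise ValueError("target size must be positive")
        self.out_height = out_height
        self.out_width = out_width
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = (h, w)
        rmat = resize_matrix(h, self.out_height).astype(core.DTYPE)
        cmat = resize_matrix(w, self.out_width).astype(core.DTYPE)
        return np.matmul(rmat, np.matmul(x, cmat.T))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._shape
        rmat = resize_matrix(h, self.out_height).astype(core.DTYPE)
        cmat = resize_matrix(w, self.out_width).astype(core.DTYPE)
        return np.matmul(rmat.T, np.matmul(grad, cmat))
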