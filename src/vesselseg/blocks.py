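"""Core operators of the gated-skip / adaptive-upsampling segmentation net.

Two families of surface live here:

* **Functional forms** operating on single feature maps shaped
  ``(channels, height, width)`` — ``gated_skip``, ``adaptive_upsample``,
  ``bilinear_resize``, ``conv_block``, ``periodic_rearrange`` and
  ``deconv_output_size``.  These are the reference semantics and what
  the oracle tests exercise.
* **Module forms** (``GatedSkip``, ``AdaptiveUp``, ``BilinearUp``,
  ``DeconvUp``, ``ConvBlock``) that carry parameters and a backward
  pass, used to assemble the full network.

A *gated skip-connection* modulates the encoder feature ``E`` with an
attention map computed from the concatenation of ``E`` and the decoder
feature ``D``::

    alpha = sigmoid(conv1x1(concat(E, D)))     # one gate per E channel
    Y     = concat(E * alpha + E, D)

*Adaptive upsampling* expands channels with a learned convolution and
then periodically rearranges each group of ``r * r`` channels into an
``r``-times larger spatial grid (sub-pixel / depth-to-space layout);
the rearrangement itself has no parameters and is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Module, PixelShuffle,
                 ReLU, Sigmoid, resize_matrix)

__all__ = [
    "GateParams", "UpsampleSpec", "gated_skip", "periodic_rearrange",
    "periodic_rearrange_inverse", "adaptive_upsample", "bilinear_resize",
    "deconv_output_size", "conv_block", "GatedSkip", "PlainSkip",
    "AdaptiveUp", "BilinearUp", "DeconvUp", "ConvBlock",
]


# --------------------------------------------------------------------------
# parameter containers for the functional forms
# --------------------------------------------------------------------------

@dataclass
class GateParams:
    """1x1-convolution weights of the sigmoid gate.

    ``weight`` has shape ``(out_channels, in_channels, 1, 1)`` with
    ``in_channels = channels(E) + channels(D)`` and
    ``out_channels = channels(E)`` (one gate value per encoder channel).
    """

    weight: np.ndarray
    bias: np.ndarray


@dataclass
class UpsampleSpec:
    """Which upsampling mechanism a decoder stage uses."""

    mode: str = "adaptive"          # adaptive | bilinear | deconv
    r: int = 2                      # subwindow factor (adaptive only)
    out_channels: int = 1

    def __post_init__(self):
        if self.mode not in ("adaptive", "bilinear", "deconv"):
            raise ValueError(f"unknown upsample mode {self.mode!r}")
        if self.r < 1:
            raise ValueError("subwindow factor r must be >= 1")


def _check_map(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"{name} must be (channels, height, width), got shape {x.shape}")
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    return x


# --------------------------------------------------------------------------
# gated skip-connection
# --------------------------------------------------------------------------

def gated_skip(E: np.ndarray, D: np.ndarray, params: GateParams) -> np.ndarray:
    """Apply the gated skip-connection to one encoder/decoder feature pair.

    Returns ``concat(E * alpha + E, D)`` with
    ``alpha = sigmoid(conv1x1(concat(E, D)))``; the output has
    ``channels(E) + channels(D)`` channels at the shared spatial size.
    """
    E = _check_map(E, "E")
    D = _check_map(D, "D")
    if E.shape[1:] != D.shape[1:]:
        raise ValueError(
            f"spatial size mismatch: E is {E.shape[1:]}, D is {D.shape[1:]}")
    ce, cd = E.shape[0], D.shape[0]
    w = np.asarray(params.weight, dtype=E.dtype)
    b = np.asarray(params.bias, dtype=E.dtype)
    if w.shape != (ce, ce + cd, 1, 1) or b.shape != (ce,):
        raise ValueError(
            f"gate parameters shaped {w.shape}/{b.shape} do not match "
            f"(out={ce}, in={ce + cd}, 1, 1)/({ce},)")
    cat = np.concatenate([E, D], axis=0)
    z = np.tensordot(w[:, :, 0, 0], cat, axes=([1], [0])) + b[:, None, None]
    alpha = 1.0 / (1.0 + np.exp(-z.astype(np.float64, copy=False)))
    gated = E * alpha.astype(E.dtype, copy=False) + E
    return np.concatenate([gated, D], axis=0)


class GatedSkip(Module):
    """Batched, differentiable gated skip-connection module."""

    def __init__(self, enc_channels: int, dec_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.enc_channels = enc_channels
        self.dec_channels = dec_channels
        self.gate = Conv2d(enc_channels + dec_channels, enc_channels, 1, rng=rng)
        self.sigmoid = Sigmoid()
        self._cache = None

    def forward(self, E: np.ndarray, D: np.ndarray) -> np.ndarray:
        if E.shape[2:] != D.shape[2:]:
            raise ValueError(
                f"spatial size mismatch: E is {E.shape[2:]}, D is {D.shape[2:]}")
        cat = np.concatenate([E, D], axis=1)
        alpha = self.sigmoid(self.gate(cat))
        self._cache = (E, alpha)
        return np.concatenate([E * alpha + E, D], axis=1)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        E, alpha = self._cache
        ce = self.enc_channels
        g_gated, g_dec = grad[:, :ce], grad[:, ce:]
        g_alpha = g_gated * E
        g_cat = self.gate.backward(self.sigmoid.backward(g_alpha))
        gE = g_gated * (alpha + 1.0) + g_cat[:, :ce]
        gD = g_dec + g_cat[:, ce:]
        self._cache = None
        return gE, gD


class PlainSkip(Module):
    """Ungated baseline: plain channelwise concatenation of E and D."""

    def __init__(self, enc_channels: int, dec_channels: int):
        super().__init__()
        self.enc_channels = enc_channels
        self.dec_channels = dec_channels

    def forward(self, E: np.ndarray, D: np.ndarray) -> np.ndarray:
        if E.shape[2:] != D.shape[2:]:
            raise ValueError(
                f"spatial size mismatch: E is {E.shape[2:]}, D is {D.shape[2:]}")
        return np.concatenate([E, D], axis=1)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ce = self.enc_channels
        return grad[:, :ce], grad[:, ce:]


# --------------------------------------------------------------------------
# adaptive upsampling (sub-pixel rearrangement)
# --------------------------------------------------------------------------

def periodic_rearrange(mid: np.ndarray, r: int) -> np.ndarray:
    """Depth-to-space: ``out[c, y, x] = mid[c*r*r + (y%r)*r + (x%r), y//r, x//r]``."""
    mid = _check_map(mid, "mid")
    c, h, w = mid.shape
    if r < 1:
        raise ValueError("subwindow factor r must be >= 1")
    if c % (r * r):
        raise ValueError(f"channel count {c} not divisible by r^2 = {r * r}")
    co = c // (r * r)
    out = mid.reshape(co, r, r, h, w).transpose(0, 3, 1, 4, 2)
    return np.ascontiguousarray(out.reshape(co, h * r, w * r))


def periodic_rearrange_inverse(out: np.ndarray, r: int) -> np.ndarray:
    """Space-to-depth, the exact inverse of :func:`periodic_rearrange`."""
    out = _check_map(out, "out")
    co, hr, wr = out.shape
    if hr % r or wr % r:
        raise ValueError(f"spatial size {hr}x{wr} not divisible by r = {r}")
    h, w = hr // r, wr // r
    mid = out.reshape(co, h, r, w, r).transpose(0, 2, 4, 1, 3)
    return np.ascontiguousarray(mid.reshape(co * r * r, h, w))


def adaptive_upsample(X: np.ndarray, spec: UpsampleSpec,
                      conv_params: tuple[np.ndarray, np.ndarray | None]) -> np.ndarray:
    """Learned channel expansion followed by periodic rearrangement.

    ``conv_params`` is ``(weight, bias)`` for a 3x3 same-padding
    convolution emitting ``spec.out_channels * r**2`` channels; ``bias``
    may be ``None``.  Returns a map of shape
    ``(out_channels, r*H, r*W)``.
    """
    if spec.mode != "adaptive":
        raise ValueError(f"spec.mode must be 'adaptive', got {spec.mode!r}")
    X = _check_map(X, "X")
    weight, bias = conv_params
    weight = np.asarray(weight, dtype=np.float32)
    r = spec.r
    want = spec.out_channels * r * r
    if weight.shape[0] != want or weight.shape[1] != X.shape[0]:
        raise ValueError(
            f"expansion conv shaped {weight.shape} must emit {want} channels "
            f"from {X.shape[0]}")
    conv = Conv2d(X.shape[0], want, weight.shape[2], padding=weight.shape[2] // 2,
                  bias=bias is not None)
    conv.weight.data[...] = weight
    if bias is not None:
        conv.bias.data[...] = np.asarray(bias, dtype=np.float32)
    mid = conv(X[None])[0]
    return periodic_rearrange(mid, r)


class AdaptiveUp(Module):
    """Decoder upsampling stage: bias-free 3x3 conv to ``r*r*out`` channels
    followed by the parameter-free periodic rearrangement."""

    def __init__(self, in_channels: int, out_channels: int, r: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels * r * r, 3, padding=1,
                           bias=False, rng=rng)
        self.shuffle = PixelShuffle(r)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.shuffle(self.conv(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.shuffle.backward(grad))


# --------------------------------------------------------------------------
# bilinear interpolation
# --------------------------------------------------------------------------

def _engine_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    return resize_matrix(n_in, n_out).astype(dtype, copy=False)


def bilinear_resize(X: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Corner-aligned bilinear resampling of a (C, H, W) feature map.

    Every output pixel is a convex combination of its four nearest
    source pixels (weights sum to one); when the target size equals the
    source size the map is returned unchanged.
    """
    X = _check_map(X, "X")
    if out_height < 1 or out_width < 1:
        raise ValueError(f"target size {out_height}x{out_width} must be positive")
    _, h, w = X.shape
    if (out_height, out_width) == (h, w):
        return X.copy()
    rmat = resize_matrix(h, out_height)
    cmat = resize_matrix(w, out_width)
    return np.matmul(rmat, np.matmul(X, cmat.T))


class BilinearUp(Module):
    """Ablation decoder stage: x2 corner-aligned bilinear resize, then a
    1x1 convolution to the stage width (the smallest-parameter option)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 1, rng=rng)
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = (h, w)
        rmat = _engine_matrix(h, 2 * h, x.dtype)
        cmat = _engine_matrix(w, 2 * w, x.dtype)
        return self.conv(np.matmul(rmat, np.matmul(x, cmat.T)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._shape
        g = self.conv.backward(grad)
        rmat = _engine_matrix(h, 2 * h, g.dtype)
        cmat = _engine_matrix(w, 2 * w, g.dtype)
        return np.matmul(rmat.T, np.matmul(g, cmat))


# --------------------------------------------------------------------------
# deconvolution (transposed convolution)
# --------------------------------------------------------------------------

def deconv_output_size(i: int, k: int, s: int, p: int, rem: int = 0) -> int:
    """Output side length of a transposed convolution.

    ``o = s*(i-1) - 2p + k`` when the stride divides evenly
    (``rem = 0``) and ``o = s*(i-1) - 2p + k + rem`` otherwise, where
    ``rem = (o + 2p - k) mod s`` is the leftover the forward convolution
    discarded (realized as asymmetric output padding).
    """
    if i < 1 or k < 1 or s < 1:
        raise ValueError("input size, kernel size and stride must be >= 1")
    if p < 0 or rem < 0:
        raise ValueError("padding and remainder must be non-negative")
    if rem >= s:
        raise ValueError(f"remainder {rem} must be smaller than stride {s}")
    return s * (i - 1) - 2 * p + k + rem


class DeconvUp(Module):
    """Ablation decoder stage: 6x6 stride-2 transposed convolution with
    padding 2 (doubles the spatial size; same 3x3-per-output-pixel tap
    footprint as the adaptive stage's expansion conv, plus a bias)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.deconv = ConvTranspose2d(in_channels, out_channels, 6,
                                      stride=2, padding=2, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.deconv(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.deconv.backward(grad)


# --------------------------------------------------------------------------
# shared convolution block
# --------------------------------------------------------------------------

class ConvBlock(Module):
    """Two 3x3 convolutions, each batch-normalized, with one ReLU.

    ``order='tail_relu'`` places the single ReLU after the second
    conv+norm pair (conv-norm-conv-norm-relu); ``order='each'`` is the
    conventional conv-norm-relu-conv-norm-relu variant.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 order: str = "tail_relu", rng: np.random.Generator | None = None):
        super().__init__()
        if order not in ("tail_relu", "each"):
            raise ValueError(f"unknown conv-block order {order!r}")
        self.order = order
        # batch-norm absorbs any constant channel shift, so the convs
        # are bias-free (a bias here would receive an exactly-zero
        # gradient and never train)
        self.conv1 = Conv2d(in_channels, out_channels, 3, padding=1,
                            bias=False, rng=rng)
        self.norm1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1,
                            bias=False, rng=rng)
        self.norm2 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.norm1(self.conv1(x))
        if self.order == "each":
            h = self.relu1(h)
        h = self.norm2(self.conv2(h))
        return self.relu2(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.norm2.backward(self.relu2.backward(grad))
        g = self.conv2.backward(g)
        if self.order == "each":
            g = self.relu1.backward(g)
        return self.conv1.backward(self.norm1.backward(g))


def conv_block(X: np.ndarray, params: "ConvBlock") -> np.ndarray:
    """Functional wrapper: run one (C, H, W) map through a ConvBlock in
    inference mode (running statistics, no side effects on grads)."""
    X = _check_map(X, "X")
    was_training = params.training
    params.eval()
    try:
        out = params(X[None])[0]
    finally:
        params.train(was_training)
    return out
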