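"""Encoder–decoder vessel segmentation network with gated skips,
multiscale inputs, and pluggable upsampling.

The encoder runs four stride-2 downsampling steps (a 48x48 patch passes
through 24, 12, 6 and a 3x3 bridge).  Downscaled copies of the input
image (1/2, 1/4, 1/8) are embedded with a 3x3 convolution and
concatenated into the matching encoder stage so the network sees every
scale directly.  Each decoder stage upsamples by 2 (adaptive /
bilinear / deconvolution, per config), merges the encoder feature
through a gated or plain skip-connection, and refines with a conv
block.  A 1x1 convolution plus sigmoid yields per-pixel vessel
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .blocks import (AdaptiveUp, BilinearUp, ConvBlock, DeconvUp, GatedSkip,
                     PlainSkip)
from .nn import Conv2d, Module, Sigmoid, resize_matrix

__all__ = ["NetworkConfig", "VesselNet", "build_network", "count_parameters",
           "save_checkpoint", "load_checkpoint"]

UPSAMPLE_MODES = ("adaptive", "bilinear", "deconv")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_width`` is the channel count of the full-resolution stage;
    widths double per stage (so 32 -> 64 -> 128 -> 256 with a
    512-channel bridge at the default).  ``r`` is the subwindow factor
    of the adaptive upsampler; with one upsampling per decoder stage it
    stays at 2.
    """

    in_channels: int = 1
    depth: int = 4
    base_width: int = 32
    upsample_mode: str = "adaptive"
    gating: bool = True
    r: int = 2
    multiscale_input: bool = True
    norm_order: str = "tail_relu"
    seed: int = 0

    def __post_init__(self):
        if self.depth != 4:
            raise ValueError("the architecture is defined for depth = 4")
        if self.upsample_mode not in UPSAMPLE_MODES:
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")
        if self.upsample_mode == "adaptive" and self.r != 2:
            raise ValueError("per-stage adaptive upsampling requires r = 2")
        if self.base_width < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be positive")


class VesselNet(Module):
    """The assembled network.  ``forward`` returns probabilities in
    [0, 1]; ``backward`` expects the gradient at the pre-sigmoid logits
    (for binary cross-entropy that gradient is simply
    ``(p - y) / n_pixels``)."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = [config.base_width * (2 ** t) for t in range(5)]  # c0..c3 + bridge
        ms = config.base_width
        order = config.norm_order

        self.stem = ConvBlock(config.in_channels, w[0], order=order, rng=rng)
        self.down = [Conv2d(w[t], w[t + 1], 3, stride=2, padding=1, rng=rng)
                     for t in range(4)]
        if config.multiscale_input:
            self.ms_conv = [Conv2d(config.in_channels, ms, 3, padding=1, rng=rng)
                            for _ in range(3)]
            enc_in = [w[t + 1] + ms for t in range(3)]
        else:
            self.ms_conv = []
            enc_in = [w[t + 1] for t in range(3)]
        self.enc_block = [ConvBlock(enc_in[t], w[t + 1], order=order, rng=rng)
                          for t in range(3)]
        self.bridge = ConvBlock(w[4], w[4], order=order, rng=rng)

        up_cls = {"adaptive": lambda i, o: AdaptiveUp(i, o, config.r, rng=rng),
                  "bilinear": lambda i, o: BilinearUp(i, o, rng=rng),
                  "deconv": lambda i, o: DeconvUp(i, o, rng=rng)}[config.upsample_mode]
        self.up = [up_cls(w[t + 1], w[t]) for t in range(4)]  # up[t]: to stage t
        if config.gating:
            self.skip = [GatedSkip(w[t], w[t], rng=rng) for t in range(4)]
        else:
            self.skip = [PlainSkip(w[t], w[t]) for t in range(4)]
        self.dec_block = [ConvBlock(2 * w[t], w[t], order=order, rng=rng)
                          for t in range(4)]
        self.head = Conv2d(w[0], 1, 1, rng=rng)
        self.out_act = Sigmoid()
        self._cache = None

    # -- forward --------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, wdt = x.shape
        div = 2 ** self.config.depth
        if h % div or wdt % div:
            raise ValueError(
                f"input size {h}x{wdt} must be divisible by {div}")
        skips = [self.stem(x)]
        feat = skips[0]
        for t in range(4):
            feat = self.down[t](feat)
            if t < 3:
                if self.config.multiscale_input:
                    scale = 2 ** (t + 1)
                    small = _resize_batch(x, h // scale, wdt // scale)
                    feat = np.concatenate([feat, self.ms_conv[t](small)], axis=1)
                feat = self.enc_block[t](feat)
                skips.append(feat)
        feat = self.bridge(feat)
        for t in (3, 2, 1, 0):
            feat = self.up[t](feat)
            feat = self.skip[t](skips[t], feat)
            feat = self.dec_block[t](feat)
        logits = self.head(feat)
        self._cache = True
        return self.out_act(logits)

    def backward(self, grad_logits: np.ndarray) -> None:
        """Backpropagate from the pre-sigmoid logits; gradients
        accumulate in the parameters.  Input-image gradients are
        discarded (the image is data, not a parameter)."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        g = self.head.backward(grad_logits)
        g_skips = [None] * 4
        for t in (0, 1, 2, 3):
            g = self.dec_block[t].backward(g)
            gE, g = self.skip[t].backward(g)
            g_skips[t] = gE
            g = self.up[t].backward(g)
        g = self.bridge.backward(g)
        for t in (3, 2, 1):
            g = self.down[t].backward(g)       # grad at encoder feature E_t
            g = g + g_skips[t]
            g = self.enc_block[t - 1].backward(g)
            if self.config.multiscale_input:
                ce = g.shape[1] - self.config.base_width
                self.ms_conv[t - 1].backward(g[:, ce:])
                g = g[:, :ce]
        g = self.down[0].backward(g)
        self.stem.backward(g + g_skips[0])
        self._cache = None

    # -- inference ------------------------------------------------------
    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Probabilities for a stack of images, in evaluation mode."""
        was_training = self.training
        self.eval()
        try:
            outs = [self.forward(images[i:i + batch_size])
                    for i in range(0, len(images), batch_size)]
        finally:
            self.train(was_training)
        return np.concatenate(outs, axis=0)


def _resize_batch(x: np.ndarray, oh: int, ow: int) -> np.ndarray:
    rmat = resize_matrix(x.shape[2], oh).astype(x.dtype, copy=False)
    cmat = resize_matrix(x.shape[3], ow).astype(x.dtype, copy=False)
    return np.matmul(rmat, np.matmul(x, cmat.T))


def build_network(config: NetworkConfig) -> VesselNet:
    """Construct the network; weight initialization is fixed by
    ``config.seed``."""
    return VesselNet(config)


def count_parameters(net: Module) -> int:
    """Total number of learnable scalars (running statistics excluded)."""
    return int(sum(p.size for p in net.parameters()))


def save_checkpoint(net: VesselNet, path: str | Path) -> None:
    """Write weights (.npz) plus a self-describing config (.json)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.state_dict())
    cfg = path.with_suffix(".json")
    cfg.write_text(json.dumps(asdict(net.config), indent=2) + "\n")


def load_checkpoint(path: str | Path) -> VesselNet:
    path = Path(path)
    config = NetworkConfig(**json.loads(path.with_suffix(".json").read_text()))
    net = build_network(config)
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
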