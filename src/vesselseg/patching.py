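"""Random-patch sampling for training and tiled inference for full images.

Training draws many small square crops (default 48x48, 10,480 per
image) with centers uniform over positions whose patch fits the image;
with ``inside_fov`` the center must additionally lie inside the FOV
mask.  At test time the trained net sees overlapping tiles of the full
image whose predictions are averaged per pixel by overlap count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchSpec", "TileSpec", "PatchSet", "sample_patches", "tile_and_stitch"]


@dataclass
class PatchSpec:
    size: int = 48
    per_image: int = 10480
    inside_fov: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("patch size must be >= 8")
        if self.per_image < 1:
            raise ValueError("per_image must be >= 1")


@dataclass
class TileSpec:
    size: int = 48
    stride: int = 24

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.stride > self.size:
            raise ValueError(
                f"stride {self.stride} must not exceed tile size {self.size}")


@dataclass
class PatchSet:
    """Paired patches: images (n, 1, s, s) float32, labels (n, 1, s, s)
    float32 in {0, 1}, plus the sampled center coordinates."""

    images: np.ndarray
    labels: np.ndarray
    centers: np.ndarray  # (n, 2) row, col


def sample_patches(image: np.ndarray, label: np.ndarray, mask: np.ndarray,
                   spec: PatchSpec) -> PatchSet:
    """Draw ``spec.per_image`` random patches (uniform with replacement).

    The valid center grid keeps every patch fully inside the image; a
    patch of even size ``s`` spans ``[c - s//2, c + s//2)`` around its
    center.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.shape != label.shape or image.shape != mask.shape:
        raise ValueError(
            f"image/label/mask sizes differ: {image.shape}, {label.shape}, {mask.shape}")
    h, w = image.shape
    s = spec.size
    if h < s or w < s:
        raise ValueError(
            f"image {h}x{w} is smaller than the patch size {s}x{s}")
    lo = s // 2
    hi_r, hi_c = h - s + lo, w - s + lo  # inclusive upper center bounds
    rng = np.random.default_rng(spec.seed)
    if spec.inside_fov:
        valid = np.zeros((h, w), dtype=bool)
        valid[lo:hi_r + 1, lo:hi_c + 1] = mask[lo:hi_r + 1, lo:hi_c + 1] > 0
        rows, cols = np.nonzero(valid)
        if rows.size == 0:
            raise ValueError("no valid FOV patch centers; mask empty in the "
                             "admissible region")
        pick = rng.integers(0, rows.size, size=spec.per_image)
        centers = np.stack([rows[pick], cols[pick]], axis=1)
    else:
        rr = rng.integers(lo, hi_r + 1, size=spec.per_image)
        cc = rng.integers(lo, hi_c + 1, size=spec.per_image)
        centers = np.stack([rr, cc], axis=1)
    imgs = np.empty((spec.per_image, 1, s, s), dtype=np.float32)
    labs = np.empty((spec.per_image, 1, s, s), dtype=np.float32)
    labelf = (np.asarray(label) > 0).astype(np.float32)
    for i, (r, c) in enumerate(centers):
        r0, c0 = r - lo, c - lo
        imgs[i, 0] = image[r0:r0 + s, c0:c0 + s]
        labs[i, 0] = labelf[r0:r0 + s, c0:c0 + s]
    return PatchSet(images=imgs, labels=labs, centers=centers)


def tile_and_stitch(image: np.ndarray, mask: np.ndarray | None, net,
                    tiles: TileSpec, batch_size: int = 64) -> np.ndarray:
    """Full-image probability map from a patch-trained network.

    The image is reflect-padded so an integer tile grid covers it,
    every tile is predicted, and overlapping predictions are averaged
    by overlap count before cropping back to the input size.  ``net``
    needs a ``predict(batch) -> probabilities`` method (or be a plain
    callable).
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    s, st = tiles.size, tiles.stride

    def padded_extent(n: int) -> int:
        if n <= s:
            return s
        return s + int(np.ceil((n - s) / st)) * st

    hp, wp = padded_extent(h), padded_extent(w)
    pad_img = np.pad(image, ((0, hp - h), (0, wp - w)), mode="reflect")
    ys = list(range(0, hp - s + 1, st))
    xs = list(range(0, wp - s + 1, st))
    batch = np.stack([pad_img[y:y + s, x:x + s] for y in ys for x in xs])[:, None]
    predict = net.predict if hasattr(net, "predict") else net
    try:
        probs = np.asarray(predict(batch, batch_size=batch_size))
    except TypeError:
        probs = np.asarray(predict(batch))
    if probs.ndim == 4:
        probs = probs[:, 0]
    acc = np.zeros((hp, wp), dtype=np.float64)
    cnt = np.zeros((hp, wp), dtype=np.float64)
    i = 0
    for y in ys:
        for x in xs:
            acc[y:y + s, x:x + s] += probs[i]
            cnt[y:y + s, x:x + s] += 1.0
            i += 1
    return (acc / cnt)[:h, :w].astype(np.float32)
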