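"""Procedural fundus-like phantoms: vessel trees, illumination, FOV.

The generator emulates what a green-channel fundus photograph offers a
segmentation network: dark curvilinear vessel trees of varying width on
a brighter, smoothly varying background, inside a circular camera field
of view.  Trees radiate from an off-center "optic disc" point as
biased random walks that branch, meander (tortuosity) and taper, so
thin-vessel cases are always present.  It makes no attempt at
photorealism (no lesions, no texture of the retinal surface).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Knobs of the phantom generator; ``seed`` fully determines output.

    ``vessel_contrast`` is how much darker vessels are than their
    surroundings (in [0, 1] intensity units); ``tortuosity`` the
    standard deviation (radians) of the per-step heading change;
    ``illumination_gradient`` the peak-to-trough amplitude of the
    smooth background field.
    """

    height: int = 584
    width: int = 565
    n_trees: int = 9
    branch_prob: float = 0.02
    width_range: tuple[int, int] = (1, 6)
    tortuosity: float = 0.18
    vessel_contrast: float = 0.45
    noise_sd: float = 0.04
    illumination_gradient: float = 0.15
    fov_radius_frac: float = 0.98
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError(
                f"phantom size {self.height}x{self.width} is degenerate (< 16 px)")
        if not (0.0 < self.fov_radius_frac <= 1.0):
            raise ValueError("fov_radius_frac must be in (0, 1]")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.tortuosity < 0:
            raise ValueError("noise_sd and tortuosity must be non-negative")
        if not (0.0 <= self.vessel_contrast <= 1.0):
            raise ValueError("vessel_contrast must be in [0, 1]")
        lo, hi = self.width_range
        if lo < 1 or hi < lo:
            raise ValueError("width_range must satisfy 1 <= lo <= hi")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class Phantom:
    """One synthetic sample: image in [0, 1], binary vessels, binary FOV."""

    image: np.ndarray
    vessels: np.ndarray
    fov: np.ndarray


def _fov_mask(h: int, w: int, radius_frac: float) -> np.ndarray:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = radius_frac * min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2)


def _stamp_disk(canvas: np.ndarray, y: float, x: float, radius: float) -> None:
    h, w = canvas.shape
    r = max(radius, 0.5)
    y0, y1 = max(int(y - r), 0), min(int(y + r) + 2, h)
    x0, x1 = max(int(x - r), 0), min(int(x + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= ((yy - y) ** 2 + (xx - x) ** 2 <= r * r)


def _draw_trees(spec: PhantomSpec, rng: np.random.Generator,
                fov: np.ndarray) -> np.ndarray:
    h, w = spec.height, spec.width
    vessels = np.zeros((h, w), dtype=bool)
    wmin, wmax = spec.width_range
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    scale = min(h, w)
    # root point plays the optic disc: off-center along a random bearing
    disc_angle = rng.uniform(0, 2 * np.pi)
    root = (cy + 0.28 * scale * np.sin(disc_angle),
            cx + 0.28 * scale * np.cos(disc_angle))
    max_len = int(1.4 * scale)
    # stack of walkers: (y, x, heading, half_width, steps_left)
    stack = []
    for _ in range(spec.n_trees):
        heading = rng.uniform(0, 2 * np.pi)
        width0 = rng.uniform(0.55 * wmax, wmax)
        stack.append([root[0], root[1], heading, width0 / 2.0,
                      int(rng.uniform(0.6, 1.0) * max_len)])
    while stack:
        y, x, heading, half_w, steps = stack.pop()
        while steps > 0:
            steps -= 1
            y += np.sin(heading)
            x += np.cos(heading)
            if not (0 <= y < h and 0 <= x < w) or not fov[int(y), int(x)]:
                break
            _stamp_disk(vessels, y, x, half_w)
            heading += rng.normal(0.0, spec.tortuosity)
            # gentle pull away from the root keeps trees radiating outward
            away = np.arctan2(y - root[0], x - root[1])
            diff = (away - heading + np.pi) % (2 * np.pi) - np.pi
            heading += 0.03 * diff
            half_w = max(half_w * 0.998, wmin / 2.0)
            if rng.random() < spec.branch_prob and half_w > 0.6 * wmin:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                stack.append([y, x, heading + sign * rng.uniform(0.4, 0.9),
                              half_w * 0.72, steps // 2 + 1])
                half_w *= 0.85
    return vessels


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fov = _fov_mask(h, w, spec.fov_radius_frac)
    vessels = _draw_trees(spec, rng, fov) & fov

    # smooth illumination: a tilted plane plus low-frequency blobs
    yy, xx = np.mgrid[:h, :w]
    tilt_angle = rng.uniform(0, 2 * np.pi)
    plane = ((yy - h / 2) * np.sin(tilt_angle) + (xx - w / 2) * np.cos(tilt_angle))
    plane = plane / max(abs(plane).max(), 1e-9)
    blobs = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8.0)
    blobs = blobs / max(abs(blobs).max(), 1e-9)
    illum = 0.62 + 0.5 * spec.illumination_gradient * plane + 0.08 * blobs

    soft = gaussian_filter(vessels.astype(np.float64), sigma=0.6)
    soft = soft / max(soft.max(), 1e-9) if soft.max() > 0 else soft
    image = illum - spec.vessel_contrast * soft
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(h, w))
    image = np.where(fov, image, 0.04 * illum)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return Phantom(image=image, vessels=vessels & fov, fov=fov)


def generate_dataset(spec: PhantomSpec, n: int, seed: int) -> list[Phantom]:
    """``n`` phantoms from per-item seeds derived deterministically from
    ``seed``; item ``i`` equals ``generate_phantom`` with that seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(replace(spec, seed=derive_seed(seed, i)))
            for i in range(n)]


def derive_seed(seed: int, index: int) -> int:
    """Stable per-item seed (kept below 2**31)."""
    return int((seed * 1_000_003 + 7919 * index + 1) % (2 ** 31))
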