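"""Reading and writing fundus segmentation datasets.

Supports the common directory conventions of the public retinal
benchmarks: paired image / manual-annotation / FOV-mask files in three
subdirectories.  The synthetic layout written by this package mirrors
the DRIVE convention (``images/``, ``1st_manual/``, ``mask/``).  When a
dataset ships no FOV masks (the STARE situation), a mask is estimated
from luminance at load time and the record is flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .synthvessel import Phantom

__all__ = ["SampleRecord", "SplitPlan", "load_dataset", "make_split",
           "read_sample", "write_dataset", "estimate_fov", "LAYOUTS"]

log = logging.getLogger(__name__)

IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif", ".ppm", ".pgm", ".bmp"}

#: subdirectory names (image, label, mask) per layout; mask=None means
#: no mask files exist and the FOV is estimated from luminance.
LAYOUTS: dict[str, tuple[str, str, str | None]] = {
    "drive": ("images", "1st_manual", "mask"),
    "synthetic": ("images", "1st_manual", "mask"),
    "chase": ("images", "1st_label", "mask"),
    "stare": ("images", "labels", None),
}


@dataclass
class SampleRecord:
    """Paths of one sample; ``mask_path`` may be None (estimated FOV)."""

    image_path: Path
    label_path: Path
    mask_path: Path | None
    split: str | None = None
    fov_estimated: bool = False
    size: tuple[int, int] = field(default=(0, 0))  # (height, width)


@dataclass
class SplitPlan:
    """How to partition records into train/test.

    ``fixed_halves`` puts the first half in training (the 40-image
    benchmark's 20/20 protocol); ``first20_rest8`` trains on the first
    20 records; ``leave_one_out`` tests on the single record ``fold``.
    """

    scheme: str = "fixed_halves"
    fold: int = 0

    def __post_init__(self):
        if self.scheme not in ("fixed_halves", "first20_rest8", "leave_one_out"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")


def _list_images(folder: Path) -> list[Path]:
    return sorted(p for p in folder.iterdir()
                  if p.suffix.lower() in IMAGE_EXTS)


def _decode_size(path: Path) -> tuple[int, int]:
    try:
        with Image.open(path) as im:
            return im.height, im.width
    except Exception as exc:
        raise OSError(f"cannot decode {path}: {exc}") from exc


def load_dataset(root: str | Path, layout: str = "synthetic") -> list[SampleRecord]:
    """Scan a dataset directory into validated :class:`SampleRecord` s.

    Files are paired by sorted order within each subdirectory (the
    benchmarks use different suffixes per folder but a shared ordering);
    every file must decode, and the three files of a sample must share
    one spatial size.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    try:
        img_dir, lab_dir, mask_dir = LAYOUTS[layout]
    except KeyError:
        raise ValueError(f"unknown layout {layout!r}; expected one of {sorted(LAYOUTS)}")
    images = _list_images(root / img_dir) if (root / img_dir).exists() else []
    if not images:
        warnings.warn(f"no images found under {root / img_dir}", stacklevel=2)
        return []
    labels = _list_images(root / lab_dir)
    if len(labels) != len(images):
        raise ValueError(
            f"{len(images)} images but {len(labels)} labels under {root}")
    masks: list[Path | None]
    if mask_dir is not None and (root / mask_dir).exists():
        masks = list(_list_images(root / mask_dir))
        if len(masks) != len(images):
            raise ValueError(
                f"{len(images)} images but {len(masks)} masks under {root}")
    else:
        masks = [None] * len(images)
        log.info("no mask directory for layout %r; FOV will be estimated", layout)
    records = []
    for img, lab, msk in zip(images, labels, masks):
        size = _decode_size(img)
        for other in (lab, msk):
            if other is not None and _decode_size(other) != size:
                raise ValueError(
                    f"size mismatch in sample {img.stem}: {img} is {size}, "
                    f"{other} is {_decode_size(other)}")
        records.append(SampleRecord(image_path=img, label_path=lab,
                                    mask_path=msk, fov_estimated=msk is None,
                                    size=size))
    return records


def estimate_fov(gray: np.ndarray, threshold: float = 0.08) -> np.ndarray:
    """FOV from luminance: threshold, then keep the largest connected
    component with holes filled (for datasets that ship no masks)."""
    cand = gray > threshold
    labeled, n = ndimage.label(cand)
    if n == 0:
        return np.ones_like(gray, dtype=bool)
    largest = np.argmax(ndimage.sum_labels(cand, labeled, range(1, n + 1))) + 1
    return ndimage.binary_fill_holes(labeled == largest)


def _to_gray(arr: np.ndarray, channel: str) -> np.ndarray:
    if arr.ndim == 2:
        return arr.astype(np.float32) / 255.0
    if channel == "green":
        return arr[:, :, 1].astype(np.float32) / 255.0
    if channel == "gray":
        return arr[:, :, :3].mean(axis=2).astype(np.float32) / 255.0
    raise ValueError(f"unknown channel mode {channel!r}")


def read_sample(record: SampleRecord, channel: str = "green"
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode one sample: (image float32 [0,1], label bool, fov bool).

    RGB images are reduced to the green channel by default (the
    standard choice for fundus vessels; vessels have the strongest
    contrast there).  Labels are binarized at the 8-bit midpoint.
    """
    image = _to_gray(np.asarray(Image.open(record.image_path)), channel)
    label = np.asarray(Image.open(record.label_path).convert("L")) > 127.5
    if record.mask_path is not None:
        fov = np.asarray(Image.open(record.mask_path).convert("L")) > 127.5
    else:
        fov = estimate_fov(image)
    if not (image.shape == label.shape == fov.shape):
        raise ValueError(
            f"sample {record.image_path.stem}: decoded sizes differ "
            f"(image {image.shape}, label {label.shape}, fov {fov.shape})")
    return image, label, fov


def write_dataset(phantoms: list[Phantom], root: str | Path) -> list[SampleRecord]:
    """Write phantoms in the synthetic (DRIVE-style) layout as 8-bit PNGs."""
    root = Path(root)
    img_dir, lab_dir, mask_dir = LAYOUTS["synthetic"]
    for sub in (img_dir, lab_dir, mask_dir):
        (root / sub).mkdir(parents=True, exist_ok=True)
    records = []
    for i, ph in enumerate(phantoms, start=1):
        name = f"{i:02d}.png"
        Image.fromarray(
            np.round(np.clip(ph.image, 0, 1) * 255).astype(np.uint8)
        ).save(root / img_dir / name)
        Image.fromarray(ph.vessels.astype(np.uint8) * 255).save(root / lab_dir / name)
        Image.fromarray(ph.fov.astype(np.uint8) * 255).save(root / mask_dir / name)
        records.append(SampleRecord(image_path=root / img_dir / name,
                                    label_path=root / lab_dir / name,
                                    mask_path=root / mask_dir / name,
                                    size=ph.image.shape))
    return records


def make_split(records: list[SampleRecord], plan: SplitPlan
               ) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Deterministic, disjoint and exhaustive train/test partition."""
    n = len(records)
    if plan.scheme == "fixed_halves":
        cut = n // 2
        train, test = records[:cut], records[cut:]
    elif plan.scheme == "first20_rest8":
        if n <= 20:
            raise ValueError(f"first20_rest8 needs > 20 records, got {n}")
        train, test = records[:20], records[20:]
    else:  # leave_one_out
        if not (0 <= plan.fold < n):
            raise ValueError(f"fold {plan.fold} out of range for {n} records")
        test = [records[plan.fold]]
        train = records[:plan.fold] + records[plan.fold + 1:]
    for r in train:
        r.split = "train"
    for r in test:
        r.split = "test"
    return train, test
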