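"""FOV-restricted evaluation of pixel classifiers.

Threshold metrics come from the confusion counts::

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F-measure   = 2 * precision * sensitivity / (precision + sensitivity)

Ratios whose denominator is zero are reported as NaN and flagged in
``MetricReport.undefined`` rather than silently set to 0.  ROC and
precision–recall curves sweep every score threshold (scikit-learn) with
trapezoidal areas.  All counting is restricted to pixels inside the
field-of-view mask.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .patching import TileSpec, tile_and_stitch

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics",
           "roc_pr", "evaluate_model", "mean_report", "write_reports"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    precision: float = float("nan")
    f_measure: float = float("nan")
    auc_roc: float = float("nan")
    auc_pr: float = float("nan")
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(pred_binary: np.ndarray, label: np.ndarray,
              fov: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts over ``fov == 1`` only."""
    pred_binary = np.asarray(pred_binary)
    label = np.asarray(label)
    fov = np.asarray(fov)
    if not (pred_binary.shape == label.shape == fov.shape):
        raise ValueError(
            f"shape mismatch: pred {pred_binary.shape}, label {label.shape}, "
            f"fov {fov.shape}")
    m = fov.astype(bool)
    p = pred_binary.astype(bool)[m]
    y = label.astype(bool)[m]
    tp = int(np.count_nonzero(p & y))
    fp = int(np.count_nonzero(p & ~y))
    fn = int(np.count_nonzero(~p & y))
    tn = int(np.count_nonzero(~p & ~y))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Threshold metrics from confusion counts; zero-denominator ratios
    are NaN with the metric name recorded in ``undefined``."""
    rep = MetricReport()
    und = rep.undefined

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            und.append(name)
            return float("nan")
        return num / den

    rep.accuracy = ratio("accuracy", counts.tp + counts.tn, counts.total)
    rep.sensitivity = ratio("sensitivity", counts.tp, counts.tp + counts.fn)
    rep.specificity = ratio("specificity", counts.tn, counts.tn + counts.fp)
    rep.precision = ratio("precision", counts.tp, counts.tp + counts.fp)
    if np.isnan(rep.precision) or np.isnan(rep.sensitivity) \
            or rep.precision + rep.sensitivity == 0:
        und.append("f_measure")
    else:
        rep.f_measure = (2 * rep.precision * rep.sensitivity
                         / (rep.precision + rep.sensitivity))
    return rep


def roc_pr(scores: np.ndarray, label: np.ndarray, fov: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC and PR curves over FOV pixels, with trapezoidal areas.

    Returns ``(roc_points, pr_points, auc_roc, auc_pr)`` where
    ``roc_points`` is an (n, 2) array of (fpr, tpr) and ``pr_points``
    an (n, 2) array of (recall, precision).
    """
    m = np.asarray(fov).astype(bool)
    s = np.asarray(scores, dtype=np.float64)[m]
    y = np.asarray(label).astype(bool)[m]
    if y.all():
        raise ValueError("cannot compute ROC: no negative (background) pixels in FOV")
    if not y.any():
        raise ValueError("cannot compute ROC: no positive (vessel) pixels in FOV")
    fpr, tpr, _ = roc_curve(y, s)
    auc_roc = float(_trapezoid_auc(fpr, tpr))
    # precision_recall_curve returns the curve with non-increasing
    # recall; integrate along that path (re-sorting would scramble
    # tied-recall points)
    prec, rec, _ = precision_recall_curve(y, s)
    auc_pr = float(_trapezoid_auc(rec, prec))
    roc_points = np.stack([fpr, tpr], axis=1)
    pr_points = np.stack([rec[::-1], prec[::-1]], axis=1)
    return roc_points, pr_points, auc_roc, auc_pr


def evaluate_model(net, test_samples, tiles: TileSpec | None = None,
                   threshold: float = 0.5, fov_restrict: bool = True
                   ) -> tuple[list[MetricReport], MetricReport]:
    """Per-image metric reports plus their unweighted mean.

    ``test_samples`` is a list of ``(image, label, fov)`` triples.  The
    net segments each full image by overlapping-tile averaging, scores
    are binarized at ``threshold`` for the confusion metrics, and all
    counting is FOV-restricted unless ``fov_restrict=False``.
    """
    if not test_samples:
        raise ValueError("test set is empty")
    tiles = tiles or TileSpec()
    reports = []
    for i, (image, label, fov) in enumerate(test_samples):
        try:
            prob = tile_and_stitch(image, fov, net, tiles)
            used_fov = fov if fov_restrict else np.ones_like(np.asarray(fov))
            rep = metrics(confusion(prob >= threshold, label, used_fov))
            _, _, rep.auc_roc, rep.auc_pr = roc_pr(prob, label, used_fov)
        except ValueError as exc:
            raise ValueError(f"evaluation failed on image {i}: {exc}") from exc
        reports.append(rep)
    return reports, mean_report(reports)


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Unweighted mean across images (the leave-one-out averaging rule);
    a metric undefined anywhere is undefined in the mean."""
    out = MetricReport()
    for f in fields(MetricReport):
        if f.name == "undefined":
            continue
        vals = [getattr(r, f.name) for r in reports]
        if any(np.isnan(v) for v in vals):
            out.undefined.append(f.name)
        else:
            setattr(out, f.name, float(np.mean(vals)))
    return out


def write_reports(reports: list[MetricReport], mean: MetricReport,
                  csv_path: str | Path | None = None,
                  json_path: str | Path | None = None) -> None:
    """Serialize per-image rows plus a mean row to CSV and/or JSON."""
    names = [f.name for f in fields(MetricReport) if f.name != "undefined"]
    rows = [{"image": str(i), **{k: r.as_dict()[k] for k in names}}
            for i, r in enumerate(reports)]
    rows.append({"image": "mean", **{k: mean.as_dict()[k] for k in names}})
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image", *names])
            writer.writeheader()
            writer.writerows(rows)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
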