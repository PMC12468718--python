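"""Confusion-matrix bookkeeping and the six segmentation metrics.

Per class (one-vs-rest over pixels) the suite reports accuracy, precision,
recall, F1, intersection-over-union (Jaccard) and the Dice similarity
coefficient.  F1 and DSC coincide per class (both equal 2TP/(2TP+FP+FN)),
and DSC = 2*IoU/(1+IoU); the tests pin both identities.  Ratios with a zero
denominator are reported as 0 and flagged as degenerate rather than NaN so
aggregation over empty classes stays stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "metric_suite",
    "weighted_f1",
    "foreground_mask",
    "image_level_labels",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel tallies."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_pixels: int

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if other.n_classes != self.n_classes:
            raise DataError("cannot add counts with different class counts")
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
            self.n_pixels + other.n_pixels,
        )


def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray, n_classes: int) -> ConfusionCounts:
    """Tally per-class TP/TN/FP/FN over all pixels of a mask pair (or batch)."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise DataError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    if pred.min() < 0 or pred.max() >= n_classes or true.min() < 0 or true.max() >= n_classes:
        raise DataError(f"mask indices must lie in [0, {n_classes - 1}]")
    # joint class-pair histogram -> one-vs-rest tallies
    joint = np.bincount(
        (true.ravel().astype(np.int64) * n_classes + pred.ravel()),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    n = int(joint.sum())
    tp = np.diag(joint).astype(np.int64)
    fn = joint.sum(axis=1) - tp
    fp = joint.sum(axis=0) - tp
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, n_pixels=n)


def _safe_div(num: np.ndarray, den: np.ndarray):
    """Elementwise num/den with 0 (and a degenerate flag) where den == 0."""
    den = np.asarray(den, dtype=np.float64)
    degenerate = den == 0
    out = np.divide(num, den, out=np.zeros_like(den), where=~degenerate)
    return out, degenerate


@dataclass
class MetricReport:
    """Per-class metric arrays plus macro and support-weighted aggregates."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    iou: np.ndarray
    dsc: np.ndarray
    supports: np.ndarray
    degenerate: np.ndarray  # boolean: any zero-denominator ratio for the class

    def per_class(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "iou": self.iou,
            "dsc": self.dsc, "support": self.supports,
        }

    def macro(self) -> dict:
        return {k: float(v.mean()) for k, v in self.per_class().items() if k != "support"}

    def weighted(self) -> dict:
        s = self.supports.astype(np.float64)
        if s.sum() == 0:
            raise DataError("total support is zero; no pixels to weight by")
        w = s / s.sum()
        return {k: float((v * w).sum()) for k, v in self.per_class().items() if k != "support"}


def metric_suite(counts: ConfusionCounts) -> MetricReport:
    """Compute the six metrics from confusion counts, per class."""
    tp, tn, fp, fn = (a.astype(np.float64) for a in (counts.tp, counts.tn, counts.fp, counts.fn))
    accuracy, d0 = _safe_div(tp + tn, tp + tn + fp + fn)
    precision, d1 = _safe_div(tp, tp + fp)
    recall, d2 = _safe_div(tp, tp + fn)
    f1, d3 = _safe_div(2.0 * precision * recall, precision + recall)
    iou, d4 = _safe_div(tp, tp + fp + fn)
    dsc, d5 = _safe_div(2.0 * tp, 2.0 * tp + fp + fn)
    return MetricReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        iou=iou, dsc=dsc, supports=counts.tp + counts.fn,
        degenerate=d0 | d1 | d2 | d3 | d4 | d5,
    )


def weighted_f1(report: MetricReport) -> float:
    """Support-weighted mean of per-class F1 (the checkpoint-selection score)."""
    s = report.supports.astype(np.float64)
    total = s.sum()
    if total == 0:
        raise DataError("total support is zero; weighted F1 undefined")
    return float((report.f1 * s).sum() / total)


def foreground_mask(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary tumor-vs-background mask from multi-class probabilities.

    The foreground probability marginalises over all tumor classes
    (``1 - p_background``), so boundary pixels whose tumor mass is split
    between lesion types are still counted as tumor.  ``probs`` is
    (N, C, H, W) with class 0 = background.
    """
    probs = np.asarray(probs)
    return (1.0 - probs[:, 0]) > threshold


def image_level_labels(masks: np.ndarray) -> np.ndarray:
    """Image-level class labels from masks: the most frequent non-background
    class per image, or 0 for an empty mask.

    Provides a secondary, classification-style view of segmentation output.
    """
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    labels = np.zeros(len(masks), dtype=np.int64)
    for i, m in enumerate(masks):
        counts = np.bincount(m.ravel())
        counts[0] = 0
        if counts.sum() > 0:
            labels[i] = counts.argmax()
    return labels
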