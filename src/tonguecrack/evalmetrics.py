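"""Segmentation and classification quality metrics.

Segmentation quality is computed from an accumulated pixel confusion
matrix ``P`` with rows = ground-truth class and columns = predicted class
(class 0 = background, class 1 = crack):

* per-class pixel accuracy (recall)  CPA_i = P_ii / sum_j P_ij
* mean pixel accuracy                MPA   = mean_i CPA_i
* per-class intersection over union  IoU_i = P_ii / (row_i + col_i - P_ii)
* mean IoU                           MIoU  = mean_i IoU_i
* frequency-weighted IoU             FWIoU = sum_i (row_i / total) IoU_i

Image-level crack decisions are summarised by sensitivity, specificity and
accuracy over (TP, FP, TN, FN) counts.  Accumulating counts first and
computing metrics once (micro-averaging) matches single-table reporting
over a test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "BinaryCounts",
    "confusion",
    "seg_metrics",
    "cls_metrics",
]


@dataclass
class ConfusionCounts:
    """Pixel confusion matrix; ``P[i, j]`` counts ground-truth class ``i``
    pixels predicted as class ``j``.  Add instances to accumulate over
    images."""

    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.int64)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError(f"P must be square, got shape {self.P.shape}")
        if (self.P < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def zeros(cls, n_classes: int = 2):
        return cls(np.zeros((n_classes, n_classes), dtype=np.int64))

    def __add__(self, other):
        return ConfusionCounts(self.P + other.P)

    @property
    def total(self) -> int:
        return int(self.P.sum())


@dataclass
class BinaryCounts:
    """Image-level decision counts; positives are cracked images."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __add__(self, other):
        return BinaryCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )

    @classmethod
    def from_pairs(cls, y_true, y_pred):
        """Counts from parallel boolean/0-1 sequences (True = cracked)."""
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            TP=int(np.sum(y_true & y_pred)),
            FP=int(np.sum(~y_true & y_pred)),
            TN=int(np.sum(~y_true & ~y_pred)),
            FN=int(np.sum(y_true & ~y_pred)),
        )


def confusion(gt, pred, n_classes: int = 2) -> ConfusionCounts:
    """Exact pixel cross-tabulation of a ground-truth and predicted mask.

    For the default binary case any nonzero pixel counts as crack, so 0/1
    and 0/255 mask conventions both work.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(
            f"ground truth shape {gt.shape} does not match prediction shape "
            f"{pred.shape}"
        )
    if n_classes == 2:
        gt = (gt > 0).astype(np.int64)
        pred = (pred > 0).astype(np.int64)
    else:
        gt = gt.astype(np.int64)
        pred = pred.astype(np.int64)
        if gt.min() < 0 or gt.max() >= n_classes or pred.min() < 0 or pred.max() >= n_classes:
            raise ValueError(f"class ids must be in [0, {n_classes})")
    counts = np.bincount(
        (gt * n_classes + pred).ravel(), minlength=n_classes * n_classes
    )
    return ConfusionCounts(counts.reshape(n_classes, n_classes))


def seg_metrics(counts: ConfusionCounts) -> dict:
    """The five segmentation metrics from accumulated pixel counts.

    Classes absent from both ground truth and prediction are excluded from
    the means; the crack-specific values assume class 1 is the crack.
    Raises on an all-zero matrix.
    """
    P = counts.P.astype(np.float64)
    total = P.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty (no pixels accumulated)")
    rows = P.sum(axis=1)
    cols = P.sum(axis=0)
    diag = np.diag(P)
    present = (rows > 0) | (cols > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cpa = np.where(rows > 0, diag / rows, np.nan)
        union = rows + cols - diag
        iou = np.where(union > 0, diag / union, np.nan)

    mpa = float(np.nanmean(np.where(present, cpa, np.nan)))
    miou = float(np.nanmean(np.where(present, iou, np.nan)))
    weights = rows / total
    fwiou = float(np.nansum(np.where(rows > 0, weights * iou, 0.0)))
    return {
        "CPA_crack": float(cpa[1]) if cpa.size > 1 else np.nan,
        "MPA": mpa,
        "IoU_crack": float(iou[1]) if iou.size > 1 else np.nan,
        "MIoU": miou,
        "FWIoU": fwiou,
    }


def cls_metrics(counts: BinaryCounts) -> dict:
    """Sensitivity, specificity and accuracy of image-level decisions.

    A zero denominator yields NaN with a warning rather than an error, so
    single-class test sets still produce a report.
    """
    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return float("nan")
        return num / den

    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    return {
        "SE": _ratio(tp, tp + fn, "sensitivity"),
        "SP": _ratio(tn, tn + fp, "specificity"),
        "ACC": _ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
    }
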