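"""Segmentation metrics: confusion counts, Se/Sp/Acc/F1 and closed-form AUC.

The AUC here is the closed form 1 - (FPR + FNR)/2 evaluated at the fixed
binarisation threshold — algebraically the mean of sensitivity and
specificity (balanced accuracy) — not a ROC sweep. A conventional
trapezoidal ROC-AUC over the probability map is available separately as
``roc_auc_sweep`` for comparison. Metrics with a zero denominator are
reported as NaN, never silently as 0, and dropped from dataset means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "f1_score",
    "auc_closed_form",
    "metrics_report",
    "binarize_prediction",
    "evaluate_dataset",
    "render_error_overlay",
    "roc_auc_sweep",
]

OVERLAY_COLOURS = {  # RGB, matching the usual vessel-error rendering
    "TP": (0, 255, 0),     # green
    "FP": (255, 0, 0),     # red
    "FN": (0, 0, 255),     # blue
    "TN": (0, 0, 0),       # black
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    se: float
    sp: float
    acc: float
    f1: float
    auc: float

    def as_percent(self) -> dict[str, float]:
        return {k: v * 100.0 for k, v in self.as_fraction().items()}

    def as_fraction(self) -> dict[str, float]:
        return {"Se": self.se, "Sp": self.sp, "Acc": self.acc,
                "F1": self.f1, "AUC": self.auc}


def _check_mask(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary")
    return arr.astype(bool)


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray,
              fov_mask: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts, restricted to the FOV when a mask is given."""
    pred = _check_mask(pred_mask, "pred_mask")
    gt = _check_mask(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if fov_mask is not None:
        fov = _check_mask(fov_mask, "fov_mask")
        if fov.shape != gt.shape:
            raise ValidationError("fov_mask shape mismatch")
        pred, gt = pred[fov], gt[fov]
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)),
        tn=int(np.sum(~pred & ~gt)),
        fp=int(np.sum(pred & ~gt)),
        fn=int(np.sum(~pred & gt)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when there are no positives."""
    d = c.tp + c.fn
    return c.tp / d if d else math.nan


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when there are no negatives."""
    d = c.tn + c.fp
    return c.tn / d if d else math.nan


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total; NaN on an empty tally."""
    return (c.tp + c.tn) / c.total if c.total else math.nan


def f1_score(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN) — the dice coefficient of the binary masks."""
    d = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / d if d else math.nan


def auc_closed_form(c: ConfusionCounts) -> float:
    """1 - (FPR + FNR)/2 at the fixed threshold; equals (Se + Sp)/2."""
    if c.fp + c.tn == 0 or c.fn + c.tp == 0:
        return math.nan
    fpr = c.fp / (c.fp + c.tn)
    fnr = c.fn / (c.fn + c.tp)
    return 1.0 - 0.5 * (fpr + fnr)


def metrics_report(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(se=sensitivity(c), sp=specificity(c), acc=accuracy(c),
                         f1=f1_score(c), auc=auc_closed_form(c))


def binarize_prediction(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Vessel mask = vessel-class probability strictly above the threshold
    (ties go to background)."""
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValidationError("probabilities must lie in [0,1]")
    return (prob_map > threshold).astype(np.uint8)


def evaluate_dataset(predictions: list[np.ndarray], ground_truths: list[np.ndarray],
                     fovs: list[np.ndarray | None] | None = None,
                     ids: list[str] | None = None,
                     pooled: bool = False) -> tuple[MetricsReport, pd.DataFrame]:
    """Per-image metrics plus the dataset summary.

    The summary is the unweighted mean of per-image metrics (NaN entries
    excluded); ``pooled=True`` instead pools pixel counts across images
    before computing the metrics once.
    """
    if len(predictions) != len(ground_truths):
        raise ValidationError("predictions and ground truths differ in length")
    if not predictions:
        raise ValidationError("nothing to evaluate")
    fovs = fovs if fovs is not None else [None] * len(predictions)
    if len(fovs) != len(predictions):
        raise ValidationError("fov list length mismatch")
    ids = ids if ids is not None else [f"img{i}" for i in range(len(predictions))]
    rows = []
    counts = []
    for sid, p, g, f in zip(ids, predictions, ground_truths, fovs):
        c = confusion(p, g, f)
        counts.append(c)
        r = metrics_report(c)
        rows.append({"id": sid, "TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn,
                     **r.as_fraction()})
    table = pd.DataFrame(rows)
    if pooled:
        tot = ConfusionCounts(tp=sum(c.tp for c in counts), tn=sum(c.tn for c in counts),
                              fp=sum(c.fp for c in counts), fn=sum(c.fn for c in counts))
        summary = metrics_report(tot)
    else:
        means = table[["Se", "Sp", "Acc", "F1", "AUC"]].mean(skipna=True)
        summary = MetricsReport(se=means["Se"], sp=means["Sp"], acc=means["Acc"],
                                f1=means["F1"], auc=means["AUC"])
    return summary, table


def render_error_overlay(pred_mask: np.ndarray, gt_mask: np.ndarray) -> np.ndarray:
    """RGB error image: TP green, FP red, FN blue, TN black."""
    pred = _check_mask(pred_mask, "pred_mask")
    gt = _check_mask(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValidationError("shape mismatch")
    out = np.zeros((*pred.shape, 3), dtype=np.uint8)
    out[pred & gt] = OVERLAY_COLOURS["TP"]
    out[pred & ~gt] = OVERLAY_COLOURS["FP"]
    out[~pred & gt] = OVERLAY_COLOURS["FN"]
    return out


def roc_auc_sweep(prob_map: np.ndarray, gt_mask: np.ndarray,
                  fov_mask: np.ndarray | None = None) -> float:
    """Conventional threshold-sweep (trapezoidal) ROC-AUC, for comparison
    with the closed-form quantity."""
    from sklearn.metrics import roc_auc_score

    gt = _check_mask(gt_mask, "gt_mask")
    p = np.asarray(prob_map, dtype=np.float64)
    if fov_mask is not None:
        f = _check_mask(fov_mask, "fov_mask")
        p, gt = p[f], gt[f]
    return float(roc_auc_score(gt.ravel().astype(int), p.ravel()))
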