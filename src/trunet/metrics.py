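"""Segmentation loss and evaluation metrics.

Five pixel-level metrics are reported: Dice coefficient, accuracy, Jaccard
similarity (JS), recall and precision.  Dice and JS obey the identity
JS = Dice / (2 - Dice).  Dataset-level numbers are means of per-image
metrics (stated in every report header).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nn import Tensor
from .nn import functional as F

METRIC_NAMES = ("dice", "acc", "js", "recall", "precision")


def soft_dice_loss(pred, target, epsilon: float = 1.0):
    """Differentiable Dice loss ``1 - (2*|X.Y| + eps) / (|X| + |Y| + eps)``.

    ``pred`` may be a numpy array (returns a float) or an autodiff
    :class:`~trunet.nn.Tensor` (returns a scalar Tensor for backprop).
    The smoothing term keeps the loss defined when both masks are empty.
    """
    if isinstance(pred, Tensor):
        if pred.shape != np.shape(target.data if isinstance(target, Tensor) else target):
            raise ValueError("soft_dice_loss: shape mismatch")
        tgt = target if isinstance(target, Tensor) else Tensor(
            np.asarray(target, dtype=pred.dtype))
        inter = F.tsum(F.mul(pred, tgt))
        denom = F.add(F.tsum(pred), F.tsum(tgt))
        num = F.add(F.mul(inter, Tensor(np.asarray(2.0, dtype=pred.dtype))),
                    Tensor(np.asarray(epsilon, dtype=pred.dtype)))
        den = F.add(denom, Tensor(np.asarray(epsilon, dtype=pred.dtype)))
        return F.sub(Tensor(np.asarray(1.0, dtype=pred.dtype)), F.div(num, den))
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("soft_dice_loss: shape mismatch")
    inter = float((pred * target).sum())
    return 1.0 - (2.0 * inter + epsilon) / (pred.sum() + target.sum() + epsilon)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixel-level confusion tallies for two binary masks of equal shape."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("confusion_counts: shape mismatch")
    for arr, name in ((pred, "pred"), (gt, "gt")):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"confusion_counts: {name} mask is not binary")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _safe_ratio(num: float, den: float, both_empty: bool) -> float:
    # convention: a 0/0 metric is perfect (1) when both masks are empty,
    # otherwise the score is 0
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Dice, accuracy, JS, recall, precision from pixel confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    both_empty = (tp + fp + fn) == 0
    return {
        "dice": _safe_ratio(2.0 * tp, 2.0 * tp + fp + fn, both_empty),
        "acc": (tp + tn) / counts.total if counts.total else 1.0,
        "js": _safe_ratio(float(tp), float(tp + fp + fn), both_empty),
        "recall": _safe_ratio(float(tp), float(tp + fn), both_empty),
        "precision": _safe_ratio(float(tp), float(tp + fp), both_empty),
    }


def mask_metrics(pred, gt) -> dict:
    return compute_metrics(confusion_counts(pred, gt))


def area_correlation(pred_areas, gt_areas) -> float:
    """Pearson correlation between predicted and reference lumen areas."""
    pred_areas = np.asarray(pred_areas, dtype=float)
    gt_areas = np.asarray(gt_areas, dtype=float)
    if pred_areas.shape != gt_areas.shape or pred_areas.ndim != 1:
        raise ValueError("area_correlation: need two equal-length 1-D arrays")
    if pred_areas.size < 2:
        raise ValueError("area_correlation: need at least two samples")
    if np.var(pred_areas) == 0 or np.var(gt_areas) == 0:
        raise ValueError("area_correlation: zero variance, correlation undefined")
    return float(stats.pearsonr(pred_areas, gt_areas).statistic)


def metrics_table(rows: list[dict], subset_label: str = "all") -> pd.DataFrame:
    """Per-image metric rows plus a mean summary row, Tables-2/3 layout."""
    df = pd.DataFrame(rows)
    summary = {k: df[k].mean() for k in METRIC_NAMES if k in df}
    summary["image_id"] = f"mean ({subset_label}, per-image)"
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
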