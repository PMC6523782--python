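"""Binary-classification evaluation: confusion counts, precision/recall/F1/
accuracy, and the ROC curve with trapezoidal auROC.

The positive class is mRNA (label 1) throughout.  The ROC sweep groups tied
scores at a single threshold, which makes the trapezoidal area equal to the
rank-based (pairwise comparison) estimator of P(score⁺ > score⁻) + ½P(tie).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "RocCurve", "confusion", "summary_metrics", "roc_auc", "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    """ROC points ordered by non-decreasing FPR, from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(np.int64)


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/FP/TN/FN with mRNA (1) as the positive class."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0 denominator); reporting 0", what)
        return 0.0
    return num / den


def summary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """precision, recall, F1 and accuracy from confusion counts.

    Degenerate denominators yield 0 with a warning rather than NaN.
    """
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    accuracy = _safe_div(c.tp + c.tn, c.total, "accuracy")
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


def roc_auc(labels, scores) -> RocCurve:
    """ROC curve and trapezoidal area under it.

    Thresholds sweep the unique score values from high to low (tied scores
    grouped); each threshold contributes one (FPR, TPR) point, with (0,0)
    and (1,1) sentinels.
    """
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores contain non-finite values")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # cumulative positives/negatives at each position; keep only the last
    # index of each tied-score run so ties share one threshold
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    last_of_run = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[last_of_run] / n_pos]
    fpr = np.r_[0.0, fps[last_of_run] / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auroc=auroc)


def evaluate(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """Full report: threshold the scores at 0.5 and add auROC."""
    s = np.asarray(scores, dtype=float)
    preds = (s >= threshold).astype(np.int64)
    out = summary_metrics(confusion(labels, preds))
    out["auroc"] = roc_auc(labels, s).auroc
    return out


def write_report(metrics: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in metrics.items()}, fh, indent=2)
        fh.write("\n")
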