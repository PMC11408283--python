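"""Binary-classification metrics for CPI evaluation.

Scalar metrics (ACC, SEN/TPR/recall, SPE, FPR, precision) are computed from
the 2x2 confusion table; ranking metrics are AUROC (Mann-Whitney convention,
ties get half credit) and AUPR (step-wise precision-recall curve, no linear
interpolation). Metrics whose denominator is zero are reported as ``None``
rather than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "confusion",
    "scalar_metrics",
    "auroc",
    "aupr",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of the four outcomes of a binary classifier."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    vals = np.unique(a)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"{name} must be binary 0/1, got values {vals}")
    return a.astype(int)


def confusion(labels, predictions) -> ConfusionCounts:
    """Confusion counts from binary labels and binary predictions."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def scalar_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, SEN, SPE, FPR and precision from confusion counts.

    Undefined ratios (zero denominator) are returned as ``None``.
    """
    if c.n == 0:
        raise ValueError("empty confusion table")
    return {
        "ACC": (c.tp + c.tn) / c.n,
        "SEN": _ratio(c.tp, c.tp + c.fn),
        "SPE": _ratio(c.tn, c.fp + c.tn),
        "FPR": _ratio(c.fp, c.fp + c.tn),
        "Precision": _ratio(c.tp, c.tp + c.fp),
    }


def auroc(labels, scores) -> float:
    """Area under the ROC curve.

    Computed as the Mann-Whitney probability that a random positive is
    scored above a random negative; tied scores count one half.
    """
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks -> half credit for ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve.

    Step-wise summation over descending score thresholds:
    ``sum((R_i - R_{i-1}) * P_i)`` — no linear interpolation between
    operating points. Tied scores enter as a single threshold.
    """
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined without positive samples")

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # threshold boundaries: last index of each distinct score
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp_cum = np.cumsum(y_sorted)[distinct]
    pred_pos = distinct + 1.0
    precision = tp_cum / pred_pos
    recall = tp_cum / n_pos
    delta_r = np.diff(np.r_[0.0, recall])
    return float(np.sum(delta_r * precision))
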