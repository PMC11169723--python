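"""Binary-classification metrics: Sn, Sp, Acc, MCC, AUC, ROC/PR curves.

Internal values are fractions (MCC in [-1, 1]); the percent scale used in
result tables is presentation only (:func:`format_percent`). The prediction
rule is score >= threshold (ties predicted positive). AUC is the
tie-corrected rank (Mann-Whitney) statistic: the probability that a random
positive outscores a random negative, ties counted 1/2.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "point_metrics",
    "auc",
    "roc_points",
    "pr_points",
    "evaluate",
    "format_percent",
]

METRIC_NAMES = ("Sn", "Sp", "Acc", "MCC", "AUC")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """The five headline metrics plus the confusion counts behind them.

    ``Sn``/``Sp`` are None when their denominator is empty (no positives /
    no negatives evaluated); MCC uses the zero-denominator -> 0 convention.
    """

    Sn: float | None
    Sp: float | None
    Acc: float
    MCC: float
    AUC: float
    counts: ConfusionCounts
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float | None]:
        return {"Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc,
                "MCC": self.MCC, "AUC": self.AUC}


def _validate(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D arrays of equal length")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return y.astype(int), s


def confusion(y_true: Sequence[int], scores: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN with predicted positive iff score >= threshold."""
    y, s = _validate(y_true, scores)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int((pred & (y == 1)).sum()),
        FP=int((pred & (y == 0)).sum()),
        TN=int((~pred & (y == 0)).sum()),
        FN=int((~pred & (y == 1)).sum()),
    )


def point_metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float, float]:
    """(Sn, Sp, Acc, MCC) from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP)),
    with MCC defined as 0 when any factor under the root vanishes.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    acc = (c.TP + c.TN) / c.total
    denom = (c.TP + c.FN) * (c.TN + c.FN) * (c.TP + c.FP) * (c.TN + c.FP)
    mcc = 0.0 if denom == 0 else (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return sn, sp, acc, mcc


def auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Tie-corrected rank AUC (Mann-Whitney U / (n_pos * n_neg))."""
    y, s = _validate(y_true, scores)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(y_true: Sequence[int], scores: Sequence[float]
               ) -> list[tuple[float, float]]:
    """(FPR, TPR) points, one per distinct threshold plus endpoints.

    The trapezoidal area under these points equals :func:`auc`.
    """
    y, s = _validate(y_true, scores)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_points(y_true: Sequence[int], scores: Sequence[float]
              ) -> list[tuple[float, float]]:
    """(recall, precision) points of the precision-recall curve."""
    y, s = _validate(y_true, scores)
    if len(set(y.tolist())) < 2:
        raise ValueError("PR curve requires both classes present")
    precision, recall, _ = precision_recall_curve(y, s)
    return list(zip(recall.tolist(), precision.tolist()))


def evaluate(y_true: Sequence[int], scores: Sequence[float],
             threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold metrics plus rank AUC."""
    c = confusion(y_true, scores, threshold)
    sn, sp, acc, mcc = point_metrics(c)
    return MetricsReport(Sn=sn, Sp=sp, Acc=acc, MCC=mcc,
                         AUC=auc(y_true, scores), counts=c, threshold=threshold)


def format_percent(value: float | None, digits: int = 2) -> str:
    """Render a fractional metric on the percent scale used in result tables."""
    return "NA" if value is None else f"{100.0 * value:.{digits}f}"
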