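"""Binary disorder-prediction metrics, ROC/PR curves, and predictor ranking.

Disordered is the positive class throughout.  The headline metrics are
balanced accuracy (mean of sensitivity and specificity), precision (PPV),
Matthews correlation coefficient, and the area under the ROC curve.
Predictors are compared by ranking them per metric with competition
("1224") ranking — tied values share the best rank and the next rank is
skipped — summing the four per-metric ranks into a cumulative score S_c,
and ranking ascending S_c the same way for the final standing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

from .energy import DISORDERED, ORDERED

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "balanced_accuracy",
    "precision",
    "mcc",
    "roc_points",
    "auc",
    "precision_recall_points",
    "rank_predictors",
]

METRIC_COLUMNS = ("acc", "ppv", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    ppv: float
    mcc: float
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.acc <= 1.0 and 0.0 <= self.ppv <= 1.0 and 0.0 <= self.auc <= 1.0):
            raise ValueError("ACC, PPV and AUC must lie in [0, 1]")
        if not -1.0 <= self.mcc <= 1.0:
            raise ValueError("MCC must lie in [-1, 1]")


def confusion_counts(
    predicted: Sequence[str], truth: Sequence[str]
) -> ConfusionCounts:
    """TP/TN/FP/FN with disordered as the positive class."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth labels must have equal length")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if t == DISORDERED:
            tp += p == DISORDERED
            fn += p == ORDERED
        elif t == ORDERED:
            fp += p == DISORDERED
            tn += p == ORDERED
        else:
            raise ValueError(f"unexpected truth label {t!r}; exclude unknowns first")
    return ConfusionCounts(tp, tn, fp, fn)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity."""
    if c.tp + c.fn == 0:
        raise ValueError("balanced accuracy undefined: no positive residues")
    if c.tn + c.fp == 0:
        raise ValueError("balanced accuracy undefined: no negative residues")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise ValueError("precision undefined: no predicted-positive residues")
    return c.tp / (c.tp + c.fp)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        logger.info("MCC denominator zero; returning 0 by convention")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def _score_arrays(
    probabilities: Sequence[float], truth: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth)
    if p.shape != y.shape:
        raise ValueError("probabilities and truth labels must align")
    return p, (y == DISORDERED).astype(int)


def roc_points(
    probabilities: Sequence[float], truth: Sequence[str]
) -> list[tuple[float, float]]:
    """(FPR, TPR) points from sweeping all distinct score thresholds."""
    p, y = _score_arrays(probabilities, truth)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes in the truth labels")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a (FPR, TPR) curve.

    With the tie-grouped threshold sweep this equals the rank statistic:
    the probability that a random positive outscores a random negative,
    counting ties as one half.
    """
    pts = sorted(points)
    fpr = np.array([x for x, _ in pts])
    tpr = np.array([y for _, y in pts])
    return float(np.trapezoid(tpr, fpr))


def precision_recall_points(
    probabilities: Sequence[float], truth: Sequence[str]
) -> list[tuple[float, float]]:
    """(recall, precision) at each distinct threshold, descending threshold.

    The sweep stops at the first threshold reaching full recall; beyond it
    precision can only degrade with no recall gain.
    """
    p, y = _score_arrays(probabilities, truth)
    if not y.any():
        raise ValueError("precision-recall requires at least one positive residue")
    prec, rec, thresholds = precision_recall_curve(y, p)
    # drop the synthetic terminal (recall 0, precision 1) point, keep one
    # point per distinct threshold, and order by descending threshold
    prec, rec = prec[:-1], rec[:-1]
    order = np.argsort(thresholds)[::-1]
    points = [(float(rec[i]), float(prec[i])) for i in order]
    for k, (r, _) in enumerate(points):
        if r >= 1.0:
            return points[: k + 1]
    return points


def metric_set(
    predicted: Sequence[str],
    truth: Sequence[str],
    probabilities: Sequence[float] | None = None,
) -> MetricSet:
    """Bundle the four headline metrics for one predictor."""
    c = confusion_counts(predicted, truth)
    auc_value = (
        auc(roc_points(probabilities, truth)) if probabilities is not None else float("nan")
    )
    return MetricSet(balanced_accuracy(c), precision(c), mcc(c), auc_value)


def _competition_rank(values: np.ndarray, ascending: bool) -> np.ndarray:
    """Competition ("1224") ranking: ties share the best rank, next skips."""
    ordered = values if ascending else -values
    return rankdata(ordered, method="min").astype(int)


def rank_predictors(metric_table: Mapping[str, MetricSet] | pd.DataFrame) -> pd.DataFrame:
    """Tie-aware competition ranking of predictors over the four metrics.

    Accepts either ``{name: MetricSet}`` or a DataFrame indexed by predictor
    with columns acc/ppv/mcc/auc.  Returns the table with per-metric rank
    columns (``rank_acc`` ...), the cumulative score ``s_c`` (sum of the
    four ranks) and ``final_rank`` (competition ranking on ascending S_c).
    Ties are detected by exact equality of the metric values as given.
    """
    if isinstance(metric_table, pd.DataFrame):
        df = metric_table.copy()
    else:
        df = pd.DataFrame(
            {
                name: {
                    "acc": m.acc,
                    "ppv": m.ppv,
                    "mcc": m.mcc,
                    "auc": m.auc,
                }
                for name, m in metric_table.items()
            }
        ).T
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric table lacks column(s): {missing}")
    if df[list(METRIC_COLUMNS)].isna().any().any():
        raise ValueError("metric table contains missing metric values")
    if len(df) < 2:
        raise ValueError("ranking needs at least two predictors")
    for col in METRIC_COLUMNS:
        df[f"rank_{col}"] = _competition_rank(df[col].to_numpy(float), ascending=False)
    df["s_c"] = sum(df[f"rank_{col}"] for col in METRIC_COLUMNS)
    df["final_rank"] = _competition_rank(df["s_c"].to_numpy(float), ascending=True)
    return df
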