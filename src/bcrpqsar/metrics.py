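"""Regression and threshold-shifted classification metrics.

The regression metrics are RMSE and the coefficient of determination
R² = 1 - SSres/SStot.  For classification use, predictions of a
continuous pIC50 are thresholded (positive class: pIC50 >= threshold,
boundary inclusive, applied identically to truth and calls) and
summarised by balanced accuracy, Matthews correlation, and a rank-based
AUC-ROC in which the continuous prediction is the score.  A 3-fold
error on the concentration scale corresponds to |ΔpIC50| <= log10(3).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .records import ValidationError

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "rmse",
    "r_squared",
    "confusion_at_threshold",
    "balanced_accuracy",
    "mcc",
    "auc_roc",
    "fold_error_fraction",
    "evaluate_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check_pair(observed, predicted, min_len=1):
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValidationError(
            f"observed/predicted shape mismatch: {y.shape} vs {yhat.shape}")
    if y.size < min_len:
        raise ValidationError(f"need at least {min_len} points")
    return y, yhat


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    y, yhat = _check_pair(observed, predicted, 1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """R² = 1 - Σ(y-ŷ)² / Σ(y-ȳ)²."""
    y, yhat = _check_pair(observed, predicted, 2)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise ValidationError("R² undefined for constant observed values")
    ssres = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssres / sstot


def confusion_at_threshold(observed: Sequence[float],
                           predicted: Sequence[float],
                           threshold: float) -> ConfusionCounts:
    y, yhat = _check_pair(observed, predicted, 1)
    truth = y >= threshold
    call = yhat >= threshold
    return ConfusionCounts(
        TP=int(np.sum(truth & call)),
        TN=int(np.sum(~truth & ~call)),
        FP=int(np.sum(~truth & call)),
        FN=int(np.sum(truth & ~call)))


def balanced_accuracy(c: ConfusionCounts) -> float:
    """BA = (sensitivity + specificity) / 2."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise ValidationError(
            "balanced accuracy undefined: one class is empty "
            f"(TP+FN={c.TP + c.FN}, TN+FP={c.TN + c.FP})")
    return 0.5 * (c.TP / (c.TP + c.FN) + c.TN / (c.TN + c.FP))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; any zero factor in the denominator gives 0."""
    denom = ((c.TP + c.FN) * (c.TP + c.FP) * (c.FN + c.TN) * (c.TN + c.FP))
    if denom == 0:
        logger.info("mcc: zero denominator factor, returning 0 by convention")
        return 0.0
    return (c.TP * c.TN - c.FN * c.FP) / math.sqrt(denom)


def auc_roc(observed: Sequence[float], predicted_scores: Sequence[float],
            threshold: float) -> Optional[float]:
    """Rank-based (Mann-Whitney) AUC of the continuous score against the
    thresholded truth; tied scores contribute 1/2.  Returns None when
    only one class is present."""
    y, s = _check_pair(observed, predicted_scores, 1)
    pos = y >= threshold
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        logger.info("auc_roc: single-class truth at threshold %s", threshold)
        return None
    ranks = rankdata(s)  # average ranks handle ties with weight 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fold_error_fraction(observed: Sequence[float],
                        predicted: Sequence[float],
                        fold: float = 3.0) -> float:
    """Fraction of predictions within a k-fold error of the observation
    on the concentration scale, i.e. |ΔpIC50| <= log10(k), boundary in."""
    y, yhat = _check_pair(observed, predicted, 1)
    tol = math.log10(fold)
    return float(np.mean(np.abs(yhat - y) <= tol + 1e-12))


@dataclass
class ThresholdMetrics:
    threshold: float
    confusion: ConfusionCounts
    ba: Optional[float]
    mcc: float
    auc: Optional[float]


@dataclass
class EvalReport:
    """Metrics for one train/test split."""

    split_id: int
    n: int
    rmse: float
    r2: float
    fold3_fraction: float
    per_threshold: List[ThresholdMetrics] = field(default_factory=list)


def evaluate_split(split_id: int,
                   observed: Sequence[float],
                   predicted: Sequence[float],
                   thresholds: Sequence[float] = (5.0, 5.5, 6.0, 6.5, 7.0)
                   ) -> EvalReport:
    """Full per-split evaluation: Eq-style RMSE/R², then BA, MCC and
    AUC at each shifted decision threshold, and the 3-fold-error
    fraction."""
    y, yhat = _check_pair(observed, predicted, 2)
    per = []
    for th in thresholds:
        c = confusion_at_threshold(y, yhat, th)
        try:
            ba = balanced_accuracy(c)
        except ValidationError:
            ba = None
        per.append(ThresholdMetrics(threshold=float(th), confusion=c,
                                    ba=ba, mcc=mcc(c),
                                    auc=auc_roc(y, yhat, th)))
    return EvalReport(split_id=split_id, n=int(y.size),
                      rmse=rmse(y, yhat), r2=r_squared(y, yhat),
                      fold3_fraction=fold_error_fraction(y, yhat),
                      per_threshold=per)
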