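"""Classifier evaluation: confusion counts, Sn/Sp/Ac/MCC, ROC/AUC,
stratified k-fold cross-validation, and specificity-anchored cutoffs.

Scores at or above a cutoff are called positive (ties positive). The
three operating thresholds High/Medium/Low are anchored at specificity
95%, 90% and 85% on a negative score sample, using a conservative order
statistic so the achieved specificity is at least the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ThresholdSet",
    "confusion",
    "metrics",
    "roc_auc",
    "kfold_cv",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    ac: float
    mcc: float
    mcc_undefined: bool = False  # zero denominator, reported as 0


@dataclass(frozen=True)
class ThresholdSet:
    """Score cutoffs anchored at Sp 95% (high), 90% (medium), 85% (low)."""

    high: float
    medium: float
    low: float

    def __post_init__(self) -> None:
        if not (self.high >= self.medium >= self.low):
            raise ValueError("thresholds must satisfy high >= medium >= low")

    def cutoff(self, level: str) -> float:
        return {"high": self.high, "medium": self.medium, "low": self.low}[level]


def _as_arrays(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError(f"scores ({s.shape}) and labels ({y.shape}) differ in length")
    return s, y


def confusion(scores: Sequence[float], labels: Sequence[int], cutoff: float) -> ConfusionCounts:
    """Confusion counts at a cutoff; score >= cutoff is called positive."""
    s, y = _as_arrays(scores, labels)
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = s >= cutoff
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); Ac = (TP+TN)/total;
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    A zero MCC denominator is reported as 0 with the flag set.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    ac = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return MetricSet(sn, sp, ac, 0.0, mcc_undefined=True)
    mcc = (c.tp * c.tn - c.fn * c.fp) / math.sqrt(denom)
    return MetricSet(sn, sp, ac, mcc)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray]:
    """AUC and the ROC polyline as an (n, 2) array of (1-Sp, Sn) points.

    Trapezoidal over all distinct cutoffs; with tied scores this equals
    the normalized Mann-Whitney statistic with half credit for ties.
    """
    s, y = _as_arrays(scores, labels)
    if np.unique(y).size < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return float(_trapezoid_auc(fpr, tpr)), np.column_stack([fpr, tpr])


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    pooled_auc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray


def kfold_cv(
    X: np.ndarray,
    y: Sequence[int],
    k: int,
    trainer: Callable[[np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]],
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold cross-validation.

    ``trainer(X_train, y_train, fold_seed)`` must return a scoring
    callable. Every item is tested exactly once; both the mean of
    per-fold AUCs and the pooled AUC over concatenated held-out scores
    are reported (pooled is the headline number).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if np.any(counts[counts > 0] < k):
        raise ValueError(f"every class needs at least k={k} members, got {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=float)
    fold_aucs: list[float] = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        scorer = trainer(X[train], y[train], seed + 1000 * (fold + 1))
        sc = np.asarray(scorer(X[test]), dtype=float)
        pooled[test] = sc
        if np.unique(y[test]).size == 2:
            fold_aucs.append(roc_auc(sc, y[test])[0])
    pooled_auc = roc_auc(pooled, y)[0]
    mean_auc = float(np.mean(fold_aucs)) if fold_aucs else float("nan")
    return CVResult(fold_aucs, mean_auc, pooled_auc, pooled, y)


def calibrate_thresholds(
    negative_scores: Sequence[float],
    targets: tuple[float, float, float] = (0.95, 0.90, 0.85),
) -> ThresholdSet:
    """Anchor High/Medium/Low cutoffs at target specificities.

    The cutoff for target Sp s is the smallest candidate score c such
    that the fraction of negatives strictly below c is at least s
    (candidates are the observed scores plus a value just above the
    maximum), so the achieved specificity is conservative: >= target.
    """
    neg = np.sort(np.asarray(negative_scores, dtype=float))
    n = neg.size
    if n < 20:
        raise ValueError(f"need >= 20 negative scores to anchor specificity, got {n}")
    candidates = np.append(np.unique(neg), np.nextafter(neg[-1], np.inf))
    cutoffs = []
    for s in targets:
        below = np.searchsorted(neg, candidates, side="left")  # count strictly below
        ok = candidates[below / n >= s]
        cutoffs.append(float(ok[0]))
    return ThresholdSet(high=cutoffs[0], medium=cutoffs[1], low=cutoffs[2])
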