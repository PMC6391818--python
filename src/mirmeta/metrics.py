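"""Confusion-matrix metrics, ROC/AUC and predictor overlap/coverage.

Conventions: on the common scaled axis *low* scores indicate positives,
so ROC sweeps call "true" below the moving threshold, and individual
predictors are judged at their scaled default cutoffs with the same
"<" convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .predictors import scaled_default_cutoff

__all__ = [
    "ConfusionCounts",
    "OverlapCoverage",
    "confusion",
    "metrics",
    "roc_auc",
    "overlap_coverage",
    "default_cutoff_calls",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class OverlapCoverage:
    """Pairwise overlap/coverage of correct calls for one class."""

    cls: str  # "positive" or "negative"
    pairwise_overlap: dict[tuple[str, str], float]
    pairwise_coverage: dict[tuple[str, str], float]
    all_inclusive_coverage: float | None  # only for >= 3 predictors


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, F1 and MCC.

    MCC with a zero denominator is 0 by convention; F1 is 0 (with a
    warning) when TP + FP + FN = 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total if counts.total else 0.0
    if tp + fp + fn == 0:
        warnings.warn("F1 undefined (no positives predicted or present); reporting 0")
        f1 = 0.0
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"sens": sens, "spec": spec, "acc": acc, "f1": f1, "mcc": float(mcc)}


def roc_auc(scores, labels, low_is_positive: bool = True):
    """ROC curve and trapezoid AUC from a threshold sweep.

    Returns (points, auc) where points is an array of (1 - specificity,
    sensitivity) rows.  ``low_is_positive`` matches the scaled-score
    orientation; ties are grouped at a single operating point.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, -s if low_is_positive else s)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def default_cutoff_calls(scaled_scores: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-predictor true/false calls at the scaled default cutoffs."""
    return {
        p: np.asarray(s, dtype=float) < scaled_default_cutoff(p)
        for p, s in scaled_scores.items()
    }


def overlap_coverage(calls: dict[str, np.ndarray], labels, cls: str = "positive") -> OverlapCoverage:
    """Fractions of a class correctly called by pairs of predictors.

    ``calls[p]`` is predictor p's boolean true-call vector on a common
    sample set.  For the chosen class: pairwise overlap is the fraction
    correctly called by *both* predictors, pairwise coverage by *at
    least one*; the all-inclusive coverage (any predictor correct) is
    reported only when three or more predictors are given.
    """
    if cls not in ("positive", "negative"):
        raise ValueError(f"cls must be 'positive' or 'negative', got {cls!r}")
    if len(calls) < 2:
        raise ValueError("overlap/coverage needs at least two predictors")
    y = np.asarray(labels).astype(bool)
    in_class = y if cls == "positive" else ~y
    total = int(in_class.sum())
    if total == 0:
        raise ValueError(f"no {cls} samples to evaluate")

    correct = {}
    for p, c in calls.items():
        c = np.asarray(c).astype(bool)
        correct[p] = (c if cls == "positive" else ~c) & in_class

    overlap, coverage = {}, {}
    for a, b in combinations(sorted(calls), 2):
        overlap[(a, b)] = int((correct[a] & correct[b]).sum()) / total
        coverage[(a, b)] = int((correct[a] | correct[b]).sum()) / total

    all_inclusive = None
    if len(calls) >= 3:
        any_correct = np.zeros(len(y), dtype=bool)
        for c in correct.values():
            any_correct |= c
        all_inclusive = int(any_correct.sum()) / total
    return OverlapCoverage(cls, overlap, coverage, all_inclusive)
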