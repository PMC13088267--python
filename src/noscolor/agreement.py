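"""Inter-rater agreement and binary-classifier evaluation statistics.

Cohen's κ corrects the observed agreement rate ``P₀`` (diagonal fraction
of a K×K confusion matrix of paired categorical calls) for the agreement
``P_e`` expected if both raters drew independently from their marginal
distributions: ``κ = (P₀ − P_e) / (1 − P_e)``.

Classifier evaluation follows the usual confusion-count definitions
(accuracy, precision, recall, F1) and a threshold-sweep ROC curve with the
group-ties-at-one-threshold convention; its trapezoidal area equals the
Mann–Whitney pairwise-win probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix", "KappaResult", "BinaryEval", "BinaryMetrics",
    "RocCurve", "cohens_kappa", "consistency_rate", "binary_metrics",
    "roc_curve", "auc", "reduce_multilabel_calls",
]

#: default reduction priority: an epithelial call dominates non-epithelial,
#: and a cancer call dominates a healthy one
DEFAULT_CALL_PRIORITY = ("cancerous", "healthy", "non-epithelial")


def reduce_multilabel_calls(calls_per_item,
                            priority: Sequence = DEFAULT_CALL_PRIORITY):
    """Reduce one-or-more categorical calls per item to a single primary call.

    Raters may assign several determinations to one image; agreement
    statistics need exactly one class per item.  The highest-priority
    class present among an item's calls wins (default: cancerous >
    healthy > non-epithelial).  Pass a different *priority* to change the
    reduction rule.
    """
    rank = {cls: i for i, cls in enumerate(priority)}
    reduced = []
    for calls in calls_per_item:
        items = [calls] if isinstance(calls, str) else list(calls)
        if not items:
            raise InputError("each item needs at least one call")
        unknown = [c for c in items if c not in rank]
        if unknown:
            raise InputError(f"calls {unknown} not in the priority order")
        reduced.append(min(items, key=lambda c: rank[c]))
    return reduced


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K count matrix; rows = first method's class, columns = second's."""

    counts: np.ndarray
    class_labels: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
            raise InputError("confusion matrix must be square, K >= 2")
        if np.any(m < 0) or not np.all(np.equal(np.mod(m, 1), 0)):
            raise InputError("counts must be non-negative integers")
        if m.sum() == 0:
            raise InputError("confusion matrix must contain observations")
        labels = (tuple(self.class_labels) if self.class_labels
                  else tuple(range(m.shape[0])))
        if len(labels) != m.shape[0]:
            raise InputError("need one label per class")
        object.__setattr__(self, "counts", m.astype(np.int64))
        object.__setattr__(self, "class_labels", labels)

    @classmethod
    def from_pairs(cls, calls_1: Sequence, calls_2: Sequence,
                   labels: Sequence | None = None) -> "ConfusionMatrix":
        """Cross-tabulate two aligned sequences of categorical calls."""
        c1, c2 = list(calls_1), list(calls_2)
        if len(c1) != len(c2) or not c1:
            raise InputError("call sequences must be non-empty, equal length")
        labs = list(labels) if labels is not None else sorted(set(c1) | set(c2))
        index = {lab: i for i, lab in enumerate(labs)}
        m = np.zeros((len(labs), len(labs)), dtype=np.int64)
        for a, b in zip(c1, c2):
            m[index[a], index[b]] += 1
        return cls(m, tuple(labs))

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), tuple(df.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.class_labels,
                     columns=self.class_labels).to_csv(path)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class KappaResult:
    p0: float
    pe: float
    kappa: float


def cohens_kappa(m: ConfusionMatrix) -> KappaResult:
    """Observed agreement, chance agreement, and Cohen's κ.

    ``P₀ = Σ n_kk / N``;  ``P_e = Σ r_k c_k / N²``;
    ``κ = (P₀ − P_e)/(1 − P_e) ∈ [−1, 1]``.  Raises
    :class:`~noscolor.errors.UndefinedMetricError` when ``P_e = 1`` (both
    raters constant on the same class).
    """
    n = m.n
    p0 = float(np.trace(m.counts)) / n
    pe = float(np.sum(m.row_marginals * m.col_marginals)) / n ** 2
    if pe >= 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return KappaResult(p0, pe, (p0 - pe) / (1.0 - pe))


def consistency_rate(m: ConfusionMatrix) -> float:
    """Observed agreement rate P₀ (diagonal fraction of the matrix)."""
    return float(np.trace(m.counts)) / m.n


@dataclass(frozen=True)
class BinaryEval:
    """Binary confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise InputError("at least one observation required")


@dataclass(frozen=True)
class BinaryMetrics:
    """Accuracy / precision / recall / F1 with an undefined-metric flag.

    A metric whose denominator is zero is reported as ``nan`` and listed in
    ``undefined`` rather than silently coerced to 0.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()


def binary_metrics(e: BinaryEval) -> BinaryMetrics:
    """Standard confusion-count metrics of a binary classifier."""
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    total = e.tp + e.fn + e.fp + e.tn
    accuracy = (e.tp + e.tn) / total
    precision = ratio(e.tp, e.tp + e.fp, "precision")
    recall = ratio(e.tp, e.tp + e.fn, "recall")
    if "precision" in undefined or "recall" in undefined:
        undefined.append("f1")
        f1 = float("nan")
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return BinaryMetrics(accuracy, precision, recall, f1, tuple(undefined))


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points from a descending threshold sweep.

    ``thresholds[0] = +inf`` anchors (0, 0); each subsequent threshold
    admits every item scoring at or above it (ties grouped), ending at
    (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "fpr", "tpr"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.thresholds.shape == self.fpr.shape == self.tpr.shape):
            raise InputError("ROC arrays must have equal length")


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve by sweeping the decision threshold over the unique scores.

    *labels* are binary (1 = positive).  Both classes must be present.
    Items with equal scores enter together at a single threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise InputError("scores and labels must be equal-length 1D")
    if not set(np.unique(y)) <= {0, 1}:
        raise InputError("labels must be binary 0/1")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    last_of_run = np.r_[np.diff(s_sorted) != 0, True]
    thresholds = np.r_[np.inf, s_sorted[last_of_run]]
    tpr = np.r_[0.0, tp[last_of_run] / n_pos]
    fpr = np.r_[0.0, fp[last_of_run] / n_neg]
    return RocCurve(thresholds, fpr, tpr)


def auc(curve: RocCurve) -> float:
    """Area under the ROC curve (trapezoidal rule over FPR)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))
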