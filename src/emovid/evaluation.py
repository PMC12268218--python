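"""Classification metrics and inter-rater agreement statistics.

Implements the evaluation battery for comparing classifiers and human raters
against ground truth on an imbalanced multi-class problem: confusion
(contingency) matrices, accuracy, unweighted average recall (UAR — the mean
of per-class recalls, with chance level 1/K), per-class one-vs-rest balanced
accuracy, Cohen's and Fleiss' kappa with the conventional verbal
interpretation bands, percentile bootstrap confidence intervals, and an exact
one-sided binomial test against chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyMatrix",
    "EvaluationReport",
    "contingency",
    "uar",
    "accuracy",
    "per_class_recall",
    "per_class_balanced_accuracy",
    "cohen_kappa",
    "fleiss_kappa",
    "kappa_label",
    "bootstrap_ci",
    "binomial_test_above_chance",
    "evaluate_predictions",
]


@dataclass
class ContingencyMatrix:
    """K x K confusion counts: entry (i, j) = items of true class i predicted j."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K with K = len(class_names)")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)
            if np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _as_indices(labels: Sequence, class_names: Sequence) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    try:
        return np.array([index[l] for l in labels], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not in class_names") from None


def contingency(truth: Sequence, pred: Sequence, class_names: Sequence) -> ContingencyMatrix:
    """Build the confusion matrix of predictions against ground truth."""
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    if len(truth) == 0:
        raise ValueError("cannot build a contingency matrix from zero items")
    ti = _as_indices(truth, class_names)
    pi = _as_indices(pred, class_names)
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyMatrix(counts, list(class_names))


def per_class_recall(A: ContingencyMatrix) -> dict:
    """Recall (sensitivity) per class; classes with no true items are omitted."""
    out = {}
    row_sums = A.counts.sum(axis=1)
    for i, name in enumerate(A.class_names):
        if row_sums[i] > 0:
            out[name] = A.counts[i, i] / row_sums[i]
    return out


def uar(A: ContingencyMatrix) -> float:
    """Unweighted average recall: mean of per-class recalls.

    Classes absent from the ground truth (zero row sum) are excluded from the
    average; chance level is 1/K for K represented classes.
    """
    recalls = per_class_recall(A)
    if not recalls:
        raise ValueError("no class has any true instance")
    return float(np.mean(list(recalls.values())))


def accuracy(A: ContingencyMatrix) -> float:
    """Fraction of items on the confusion-matrix diagonal."""
    return float(np.trace(A.counts) / A.n)


def per_class_balanced_accuracy(A: ContingencyMatrix) -> dict:
    """One-vs-rest (sensitivity + specificity)/2 per class.

    A class with neither true nor predicted instances is undefined and
    omitted from the result.
    """
    out = {}
    total = A.n
    row = A.counts.sum(axis=1)
    col = A.counts.sum(axis=0)
    for i, name in enumerate(A.class_names):
        tp = A.counts[i, i]
        fn = row[i] - tp
        fp = col[i] - tp
        tn = total - tp - fn - fp
        if row[i] == 0 and col[i] == 0:
            continue
        sens = tp / row[i] if row[i] > 0 else 0.0
        spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
        out[name] = float((sens + spec) / 2)
    return out


def cohen_kappa(r1: Sequence, r2: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement of two raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the product of marginals.
    If both raters are constant and identical (p_e = 1), kappa is 1 by
    convention; constant-but-different raters have non-overlapping marginals
    (p_e = 0) and score 0.
    """
    if len(r1) != len(r2) or len(r1) == 0:
        raise ValueError("raters must have equal, nonzero length")
    cats = sorted({*r1, *r2}, key=repr)
    A = contingency(r1, r2, cats)
    n = A.n
    p_o = np.trace(A.counts) / n
    p_e = float(A.counts.sum(axis=1) @ A.counts.sum(axis=0)) / n**2
    if p_e >= 1.0 - 1e-15:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1 but raters differ")
    return float((p_o - p_e) / (1 - p_e))


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for a fixed number of raters per item.

    ``ratings`` is an (n_items, n_raters) array of category labels (any
    hashable values).  Unanimous raters on every item give kappa 1.
    """
    ratings = np.asarray(ratings, dtype=object)
    if ratings.ndim != 2 or ratings.shape[0] < 1 or ratings.shape[1] < 2:
        raise ValueError("ratings must be (n_items >= 1) x (n_raters >= 2)")
    n_items, n_raters = ratings.shape
    cats = sorted({x for row in ratings for x in row}, key=repr)
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((n_items, len(cats)), dtype=np.int64)
    for i in range(n_items):
        for x in ratings[i]:
            counts[i, idx[x]] += 1
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    P_i = (np.sum(counts * (counts - 1), axis=1)) / (n_raters * (n_raters - 1))
    P_bar = P_i.mean()
    P_e = float(np.sum(p_j**2))
    if P_e >= 1.0 - 1e-15:
        return 1.0 if P_bar >= 1.0 - 1e-15 else float("nan")
    return float((P_bar - P_e) / (1 - P_e))


#: Conventional verbal interpretation bands for kappa.
_KAPPA_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (float("inf"), "almost perfect"),
)


def kappa_label(kappa: float) -> str:
    """Verbal band: slight (<=0.2), fair (<=0.4), moderate (<=0.6),
    substantial (<=0.8), almost perfect (>0.8)."""
    for upper, name in _KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "almost perfect"


def bootstrap_ci(
    truth: Sequence,
    pred: Sequence,
    metric: Callable[[Sequence, Sequence], float],
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a paired metric over item resamples."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(truth) != len(pred) or len(truth) == 0:
        raise ValueError("truth and pred must have equal, nonzero length")
    rng = np.random.default_rng(seed)
    n = len(truth)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals[b] = metric(truth[idx], pred[idx])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def binomial_test_above_chance(n_correct: int, n: int, p0: float) -> float:
    """Exact one-sided (upper tail) binomial p-value for accuracy above chance."""
    if not 0 <= n_correct <= n or n == 0:
        raise ValueError("need 0 <= n_correct <= n, n > 0")
    return float(stats.binomtest(n_correct, n, p0, alternative="greater").pvalue)


@dataclass
class EvaluationReport:
    """Full scorecard of one rater or model against ground truth."""

    accuracy: float
    uar: float
    per_class_balanced_accuracy: dict
    per_class_recall: dict
    cohen_kappa: float
    ci_low: float
    ci_high: float
    p_above_chance: float
    kappa_label: str
    n: int
    confusion: ContingencyMatrix

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "uar": self.uar,
            "per_class_balanced_accuracy": {
                str(k): v for k, v in self.per_class_balanced_accuracy.items()
            },
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "cohen_kappa": self.cohen_kappa,
            "accuracy_ci": [self.ci_low, self.ci_high],
            "p_above_chance": self.p_above_chance,
            "kappa_label": self.kappa_label,
        }


def evaluate_predictions(
    truth: Sequence,
    pred: Sequence,
    class_names: Sequence,
    chance_p0: Optional[float] = None,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Compute the full evaluation battery for one prediction series.

    ``chance_p0`` defaults to 1/K for K classes and is used for the one-sided
    binomial test on accuracy.
    """
    A = contingency(truth, pred, class_names)
    if chance_p0 is None:
        chance_p0 = 1.0 / len(class_names)
    acc = accuracy(A)
    n_correct = int(np.trace(A.counts))
    kap = cohen_kappa(list(truth), list(pred))
    lo, hi = bootstrap_ci(
        truth, pred, lambda t, p: accuracy(contingency(t, p, class_names)),
        B=bootstrap_B, seed=seed,
    )
    return EvaluationReport(
        accuracy=acc,
        uar=uar(A),
        per_class_balanced_accuracy=per_class_balanced_accuracy(A),
        per_class_recall=per_class_recall(A),
        cohen_kappa=kap,
        ci_low=lo,
        ci_high=hi,
        p_above_chance=binomial_test_above_chance(n_correct, A.n, chance_p0),
        kappa_label=kappa_label(kap),
        n=A.n,
        confusion=A,
    )
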