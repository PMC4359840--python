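"""Evaluation protocol: per-class metrics, repeated stratified k-fold CV,
the 0.632 bootstrap, Friedman and Wilcoxon signed-rank tests, reduction
ratio, and MMSE/MoCA cut-off baselines.

The resampling harness accepts any sklearn-style classifier (fit / predict
on categorical arrays).  The 0.632 bootstrap combines resubstitution and
out-of-bag performance with Efron's weights: for each repetition both
confusion matrices are normalised to proportions and mixed as

    combined = 0.368 * in-bag + 0.632 * out-of-bag

so the combined error satisfies the convex identity (equal component errors
give the same combined error).  The rank tests are implemented here with
mid-ranks and tie corrections — the exact signed-rank distribution is
computed by dynamic programming for n <= 25 — and are cross-checked against
independent implementations in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, KFold

from .table import DecisionTable, TableError

__all__ = [
    "EvaluationError",
    "EvaluationReport",
    "StatTestResult",
    "metrics_from_confusion",
    "cross_validate",
    "bootstrap_632",
    "friedman_test",
    "wilcoxon_signed_rank",
    "reduction_ratio",
    "cutoff_baseline",
    "TotalScoreCutoffClassifier",
]


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame
    recall_per_class: dict[str, float | None]
    precision_per_class: dict[str, float | None]
    accuracy: float
    scheme: str
    repetitions: int
    seed: int | None
    per_repetition_accuracy: list[float] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "scheme": self.scheme,
            "repetitions": self.repetitions,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "recall_per_class": self.recall_per_class,
            "precision_per_class": self.precision_per_class,
            "confusion": {
                "labels": list(self.confusion.index),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "per_repetition_accuracy": self.per_repetition_accuracy,
            "extras": self.extras,
        }

    def to_text(self) -> str:
        """Aligned plain-text table: per-class recall/precision plus accuracy."""
        labels = list(self.confusion.index)
        lines = [f"scheme: {self.scheme}  (repetitions={self.repetitions})"]
        lines.append(f"{'class':<12}{'R(%)':>10}{'P(%)':>10}")
        for lab in labels:
            r = self.recall_per_class.get(lab)
            p = self.precision_per_class.get(lab)
            rs = f"{100 * r:.2f}" if r is not None else "undef"
            ps = f"{100 * p:.2f}" if p is not None else "undef"
            lines.append(f"{lab:<12}{rs:>10}{ps:>10}")
        lines.append(f"{'ACC(%)':<12}{100 * self.accuracy:>10.2f}")
        return "\n".join(lines)


@dataclass
class StatTestResult:
    statistic: float
    df: int | None
    p_value: float
    mean_ranks: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def metrics_from_confusion(confusion) -> dict:
    """Recall/precision per class and accuracy from a confusion matrix
    (rows = truth).  Zero-denominator entries are reported as None, not 0."""
    if isinstance(confusion, pd.DataFrame):
        labels = [str(c) for c in confusion.index]
        if [str(c) for c in confusion.columns] != labels:
            raise EvaluationError("confusion row/column labels differ")
        mat = confusion.to_numpy(dtype=float)
    else:
        mat = np.asarray(confusion, dtype=float)
        labels = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise EvaluationError("confusion matrix must be square")
    if (mat < 0).any():
        raise EvaluationError("confusion matrix must be non-negative")
    total = mat.sum()
    if total == 0:
        raise EvaluationError("confusion matrix is all-zero")
    recall: dict[str, float | None] = {}
    precision: dict[str, float | None] = {}
    for i, lab in enumerate(labels):
        rs = mat[i].sum()
        cs = mat[:, i].sum()
        recall[lab] = float(mat[i, i] / rs) if rs > 0 else None
        precision[lab] = float(mat[i, i] / cs) if cs > 0 else None
    return {
        "recall": recall,
        "precision": precision,
        "accuracy": float(np.trace(mat) / total),
    }


def _mean_optional(values: Sequence[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# resampling schemes
# ---------------------------------------------------------------------------

def _table_xy(table: DecisionTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    return table.X(), table.y(), list(table.class_labels)


def cross_validate(
    table: DecisionTable,
    estimator,
    k: int = 10,
    repetitions: int = 10,
    seed: int | None = None,
    stratified: bool = True,
) -> EvaluationReport:
    """Repeated (stratified) k-fold CV; metrics are means over repetitions
    of the per-repetition pooled confusion matrix."""
    if k < 2:
        raise EvaluationError("k must be >= 2")
    X, y, labels = _table_xy(table)
    if stratified:
        counts = pd.Series(y).value_counts()
        if counts.min() < k:
            raise EvaluationError(
                f"smallest class has {counts.min()} members < k={k}; "
                "use a smaller k"
            )
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repetitions)
    confusions = []
    accs = []
    recalls = []
    precisions = []
    for rs in rep_seeds:
        splitter = (StratifiedKFold if stratified else KFold)(
            n_splits=k, shuffle=True, random_state=int(rs)
        )
        pooled = np.zeros((len(labels), len(labels)), dtype=float)
        for train_idx, test_idx in splitter.split(X, y):
            clf = clone(estimator)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            pooled += confusion_matrix(y[test_idx], pred, labels=labels)
        m = metrics_from_confusion(pd.DataFrame(pooled, index=labels, columns=labels))
        confusions.append(pooled)
        accs.append(m["accuracy"])
        recalls.append(m["recall"])
        precisions.append(m["precision"])
    mean_conf = pd.DataFrame(np.mean(confusions, axis=0), index=labels, columns=labels)
    return EvaluationReport(
        confusion=mean_conf,
        recall_per_class={
            lab: _mean_optional([r[lab] for r in recalls]) for lab in labels
        },
        precision_per_class={
            lab: _mean_optional([p[lab] for p in precisions]) for lab in labels
        },
        accuracy=float(np.mean(accs)),
        scheme="10-fold CV" if k == 10 else f"{k}-fold CV",
        repetitions=repetitions,
        seed=seed,
        per_repetition_accuracy=[float(a) for a in accs],
    )


def bootstrap_632(
    table: DecisionTable,
    estimator,
    repetitions: int = 10,
    seed: int | None = None,
    max_redraws: int = 100,
) -> EvaluationReport:
    """Efron's 0.632 bootstrap: per repetition, train on an n-out-of-n draw
    with replacement, score on the draw (resubstitution) and on the
    out-of-bag objects, and mix the proportion-normalised confusion matrices
    with weights 0.368 / 0.632."""
    if repetitions < 1:
        raise EvaluationError("repetitions must be >= 1")
    X, y, labels = _table_xy(table)
    n = len(y)
    n_class = len(labels)
    rng = np.random.default_rng(seed)
    confusions = []
    accs, recalls, precisions = [], [], []
    err_components = []
    oob_fractions = []
    for _ in range(repetitions):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(np.unique(y[idx])) == n_class and oob.size > 0:
                break
            warnings.warn("bootstrap draw missed a class; redrawing", stacklevel=2)
        else:
            raise EvaluationError(
                f"could not draw a bootstrap sample with all classes in "
                f"{max_redraws} redraws"
            )
        oob_fractions.append(oob.size / n)
        clf = clone(estimator)
        clf.fit(X[idx], y[idx])
        conf_in = confusion_matrix(y[idx], clf.predict(X[idx]), labels=labels).astype(float)
        conf_oob = confusion_matrix(y[oob], clf.predict(X[oob]), labels=labels).astype(float)
        acc_in = np.trace(conf_in) / conf_in.sum()
        acc_oob = np.trace(conf_oob) / conf_oob.sum()
        combined = 0.368 * conf_in / conf_in.sum() + 0.632 * conf_oob / conf_oob.sum()
        m = metrics_from_confusion(pd.DataFrame(combined, index=labels, columns=labels))
        confusions.append(combined)
        accs.append(m["accuracy"])
        recalls.append(m["recall"])
        precisions.append(m["precision"])
        err_components.append(
            {"err_train": float(1 - acc_in), "err_oob": float(1 - acc_oob)}
        )
    mean_conf = pd.DataFrame(np.mean(confusions, axis=0), index=labels, columns=labels)
    return EvaluationReport(
        confusion=mean_conf,
        recall_per_class={
            lab: _mean_optional([r[lab] for r in recalls]) for lab in labels
        },
        precision_per_class={
            lab: _mean_optional([p[lab] for p in precisions]) for lab in labels
        },
        accuracy=float(np.mean(accs)),
        scheme="0.632 bootstrap",
        repetitions=repetitions,
        seed=seed,
        per_repetition_accuracy=[float(a) for a in accs],
        extras={
            "error_components": err_components,
            "mean_oob_fraction": float(np.mean(oob_fractions)),
        },
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def friedman_test(
    score_matrix, group_labels: Sequence[str] | None = None
) -> StatTestResult:
    """Friedman rank test over a blocks x groups score matrix.

    Mid-ranks within each block; tie-corrected chi-square statistic with
    k - 1 degrees of freedom and asymptotic p-value.
    """
    a = np.asarray(score_matrix, dtype=float)
    if a.ndim != 2:
        raise EvaluationError("score matrix must be 2-D (blocks x groups)")
    n, k = a.shape
    if k < 2 or n < 2:
        raise EvaluationError("need >= 2 groups and >= 2 blocks")
    if group_labels is None:
        group_labels = [f"g{j}" for j in range(k)]
    ranks = np.apply_along_axis(stats.rankdata, 1, a)
    mean_ranks = ranks.mean(axis=0)
    ssbn = float((ranks.sum(axis=0) ** 2).sum())
    chisq = 12.0 / (k * n * (k + 1)) * ssbn - 3 * n * (k + 1)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (k * (k * k - 1) * n)
    if correction <= 0:
        return StatTestResult(
            statistic=0.0, df=k - 1, p_value=1.0,
            mean_ranks=dict(zip(group_labels, mean_ranks)),
        )
    statistic = chisq / correction
    statistic = max(statistic, 0.0)
    return StatTestResult(
        statistic=float(statistic),
        df=k - 1,
        p_value=float(stats.chi2.sf(statistic, k - 1)),
        mean_ranks={lab: float(r) for lab, r in zip(group_labels, mean_ranks)},
    )


def _signed_rank_exact_cdf(ranks: np.ndarray) -> np.ndarray:
    """Counts of W+ = w over all 2^n sign patterns, by subset-sum DP.

    Valid when the ranks are the integers 1..n (no ties)."""
    total = int(ranks.sum())
    cnt = np.zeros(total + 1, dtype=float)
    cnt[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(cnt)
        shifted[r:] = cnt[:-r] if r > 0 else cnt
        cnt = cnt + shifted
    return cnt


def wilcoxon_signed_rank(
    x,
    y=None,
    alternative: str = "two-sided",
    correction: bool = True,
) -> StatTestResult:
    """Wilcoxon signed-rank test for paired samples (or one sample of
    differences).

    Zero differences are dropped; mid-ranks are used for tied magnitudes.
    The exact null distribution (dynamic programming over 2^n sign
    assignments) is used for n <= 25 without ties, otherwise a normal
    approximation with tie-corrected variance and optional continuity
    correction.  Two-sided statistic is min(W+, W-); one-sided is W+.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise EvaluationError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    if y is None:
        d = x
    else:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise EvaluationError("paired samples must have equal length")
        d = x - y
    if len(d) < 1:
        raise EvaluationError("need at least one pair")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return StatTestResult(statistic=0.0, df=None, p_value=1.0)
    r = stats.rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    w_minus = float(r[d < 0].sum())
    has_ties = len(np.unique(np.abs(d))) != n
    statistic = min(w_plus, w_minus) if alternative == "two-sided" else w_plus

    if n <= 25 and not has_ties:
        cnt = _signed_rank_exact_cdf(r)
        total = cnt.sum()  # 2^n
        t = int(round(w_plus))
        p_le = cnt[: t + 1].sum() / total
        p_ge = cnt[t:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
        return StatTestResult(statistic=statistic, df=None, p_value=float(p))

    mn = n * (n + 1) * 0.25
    se = n * (n + 1) * (2 * n + 1)
    _, repnum = np.unique(r, return_counts=True)
    repnum = repnum[repnum > 1].astype(float)
    if repnum.size != 0:
        se -= 0.5 * float((repnum**3 - repnum).sum())
    se = math.sqrt(se / 24.0)
    T = statistic
    if correction:
        if alternative == "two-sided":
            shift = 0.5 * np.sign(T - mn)
        elif alternative == "greater":
            shift = 0.5
        else:
            shift = -0.5
    else:
        shift = 0.0
    z = (T - mn - shift) / se
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return StatTestResult(statistic=statistic, df=None, p_value=float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# reduction ratio and scale cut-off baselines
# ---------------------------------------------------------------------------

def reduction_ratio(m: int, n: int) -> float:
    """Percentage of attributes removed: (m - n) / m * 100."""
    if m < 1:
        raise EvaluationError("m must be >= 1")
    if n < 0 or n > m:
        raise EvaluationError("need m >= n >= 0")
    return (m - n) / m * 100.0


def cutoff_baseline(
    total_score: int, instrument: str, moca_ad_cutoff: int = 17
) -> str:
    """Three-class staging of a 30-point screening total by published
    cut-offs.

    MMSE: >= 27 Normal; 19-26 MCI (the published mild band extended to
    cover 25-26 so the mapping is total); <= 18 AD (moderate and severe
    impairment).  MoCA: >= 26 Normal; below that, scores above
    ``moca_ad_cutoff`` are MCI and scores at or below it are AD (the
    instrument publishes only the single cut-off at 26).
    """
    score = int(total_score)
    if not 0 <= score <= 30:
        raise EvaluationError(f"score {score} outside [0, 30]")
    if instrument.upper() == "MMSE":
        if score >= 27:
            return "Normal"
        if score >= 19:
            return "MCI"
        return "AD"
    if instrument.upper() == "MOCA":
        if score >= 26:
            return "Normal"
        if score > moca_ad_cutoff:
            return "MCI"
        return "AD"
    raise EvaluationError(f"unknown instrument {instrument!r}")


class TotalScoreCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Baseline comparator: sum all item scores, rescale to the 30-point
    range learned from training data, and stage by published cut-offs.

    Only meaningful on cohorts labelled with Normal / MCI / AD.
    """

    def __init__(self, instrument: str = "MoCA", moca_ad_cutoff: int = 17):
        self.instrument = instrument
        self.moca_ad_cutoff = moca_ad_cutoff

    @staticmethod
    def _totals(X) -> np.ndarray:
        arr = np.asarray(X)
        vals = np.empty(arr.shape, dtype=float)
        for j in range(arr.shape[1]):
            try:
                vals[:, j] = [float(v) for v in arr[:, j]]
            except ValueError as exc:  # non-numeric token
                raise EvaluationError(
                    f"cut-off baseline needs numeric item scores (column {j})"
                ) from exc
        return vals.sum(axis=1)

    def fit(self, X, y):
        totals = self._totals(X)
        self.max_total_ = float(totals.max()) if totals.max() > 0 else 1.0
        self.classes_ = np.unique(np.asarray(y, dtype=object))
        return self

    def predict(self, X):
        totals = self._totals(X)
        scaled = np.clip(np.rint(totals / self.max_total_ * 30), 0, 30).astype(int)
        return np.asarray(
            [cutoff_baseline(s, self.instrument, self.moca_ad_cutoff) for s in scaled],
            dtype=object,
        )
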