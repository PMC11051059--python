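"""Outcome metrics and the statistical-analysis plan.

Confusion metrics (sensitivity, specificity, precision, accuracy) carry
exact two-sided Clopper-Pearson 95% confidence intervals; the AUC carries
a DeLong CI (nonparametric structural-components variance). The cutoff
optimizer balances sensitivity and specificity on the midpoint grid of
observed scores. Group comparisons follow the classic EZR/R workflow: an
F-test of variance equality paired with Student's pooled-variance t-test
for continuous variables, and two-sided Fisher exact tests
(point-probability summation, R's convention) for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    """Invalid metric inputs (bad counts, single-class labels)."""


# -- exact binomial CI ----------------------------------------------------

def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (beta-quantile) two-sided binomial confidence interval."""
    if n < 1 or not 0 <= successes <= n:
        raise EvaluationError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


# -- confusion metrics ----------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricValue:
    estimate: float
    ci_lower: float
    ci_upper: float
    successes: int
    n: int


@dataclass
class MetricsReport:
    cutoff: float
    counts: ConfusionCounts
    sensitivity: MetricValue
    specificity: MetricValue
    precision: MetricValue | None  # None when no positive predictions
    accuracy: MetricValue
    auc: MetricValue | None = None
    n_positive: int = 0
    n_negative: int = 0

    def to_dict(self) -> dict:
        def mv(m: MetricValue | None):
            if m is None:
                return None
            return {
                "estimate": m.estimate,
                "ci95": [m.ci_lower, m.ci_upper],
                "successes": m.successes,
                "n": m.n,
            }

        return {
            "cutoff": self.cutoff,
            "counts": vars(self.counts),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "sensitivity": mv(self.sensitivity),
            "specificity": mv(self.specificity),
            "precision": mv(self.precision),
            "accuracy": mv(self.accuracy),
            "auc": mv(self.auc),
        }


def _binomial_metric(successes: int, n: int, level: float) -> MetricValue:
    lo, hi = clopper_pearson_ci(successes, n, level)
    return MetricValue(successes / n, lo, hi, successes, n)


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff  # a score equal to the cutoff predicts positive
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def metrics_with_ci(
    scores, labels, cutoff: float, level: float = 0.95, with_auc: bool = True
) -> MetricsReport:
    """Full metrics report at a cutoff; each binomial metric gets an exact
    Clopper-Pearson CI (precision over the predicted-positive denominator),
    the AUC a DeLong CI."""
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present")
    c = confusion_at_cutoff(scores, labels, cutoff)
    precision = None
    if c.tp + c.fp > 0:
        precision = _binomial_metric(c.tp, c.tp + c.fp, level)
    auc = None
    if with_auc:
        a, lo, hi = auc_delong(scores, labels, level)
        auc = MetricValue(a, lo, hi, 0, n_pos + n_neg)
    return MetricsReport(
        cutoff=cutoff,
        counts=c,
        sensitivity=_binomial_metric(c.tp, c.tp + c.fn, level),
        specificity=_binomial_metric(c.tn, c.tn + c.fp, level),
        precision=precision,
        accuracy=_binomial_metric(c.tp + c.tn, c.n, level),
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


# -- AUC with DeLong CI ---------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_delong(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC (Mann-Whitney with half credit for ties) and its DeLong CI.

    Variance from the structural components: V10 over positives, V01 over
    negatives; the normal-approximation CI is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise EvaluationError("AUC needs both classes present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return float(auc), max(0.0, float(auc - z * se)), min(1.0, float(auc + z * se))


# -- cutoff optimization --------------------------------------------------

def optimize_cutoff(scores, labels) -> float:
    """The midpoint-grid cutoff minimizing |sensitivity - specificity|;
    ties broken toward higher Youden index, then toward the lower cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("cutoff optimization needs both classes")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    grid = (uniq[:-1] + uniq[1:]) / 2.0
    best_cut, best_key = None, None
    for cut in grid:
        c = confusion_at_cutoff(scores, labels, cut)
        sens = c.tp / (c.tp + c.fn)
        spec = c.tn / (c.tn + c.fp)
        key = (abs(sens - spec), -(sens + spec - 1.0), cut)
        if best_key is None or key < best_key:
            best_key, best_cut = key, float(cut)
    return best_cut


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC coordinates (FPR, TPR, threshold) over all score thresholds."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


# -- group comparison tests -----------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by point-probability summation over all
    tables with the observed margins (R's convention)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise EvaluationError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def variance_then_t_test(
    a, b, welch: bool = False
) -> tuple[float | None, float | None]:
    """(F-test p, t-test p), both two-sided.

    The F-test compares variances; the t-test is Student's pooled-variance
    version by default (``welch=True`` switches to Welch). Degenerate
    zero-variance-in-both-groups inputs report missing (None).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EvaluationError("each group needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return None, None
    f_p = None
    if va > 0 and vb > 0:
        f_stat = va / vb
        dfa, dfb = a.size - 1, b.size - 1
        cdf = stats.f.cdf(f_stat, dfa, dfb)
        f_p = float(2.0 * min(cdf, 1.0 - cdf))
    t_p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return f_p, t_p


@dataclass
class GroupComparisonTable:
    """Table-3-style per-variable comparison between two groups."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def compare_groups(
    df: pd.DataFrame,
    group_col: str,
    continuous: list[str],
    categorical: list[str],
) -> GroupComparisonTable:
    """Mean +/- sd with F/t tests for continuous variables; counts with a
    Fisher exact test for binary categorical ones. Missing values are
    excluded pairwise and their counts reported alongside."""
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise EvaluationError(f"expected 2 groups, found {groups}")
    g0 = df[df[group_col] == groups[0]]
    g1 = df[df[group_col] == groups[1]]
    table = GroupComparisonTable()
    for var in continuous:
        a, b = g0[var].dropna(), g1[var].dropna()
        f_p, t_p = variance_then_t_test(a, b)
        table.rows.append(
            {
                "variable": var,
                f"{groups[0]}_mean_sd": f"{a.mean():.1f} +/- {a.std(ddof=1):.1f}",
                f"{groups[1]}_mean_sd": f"{b.mean():.1f} +/- {b.std(ddof=1):.1f}",
                "f_test_p": f_p,
                "t_test_p": t_p,
                "fisher_p": None,
                f"{groups[0]}_missing": int(g0[var].isna().sum()),
                f"{groups[1]}_missing": int(g1[var].isna().sum()),
            }
        )
    for var in categorical:
        a, b = g0[var].dropna(), g1[var].dropna()
        levels = sorted(set(a.unique()) | set(b.unique()))
        if len(levels) != 2:
            raise EvaluationError(f"{var}: Fisher test needs exactly 2 levels, got {levels}")
        t2 = [
            [int((a == levels[0]).sum()), int((a == levels[1]).sum())],
            [int((b == levels[0]).sum()), int((b == levels[1]).sum())],
        ]
        table.rows.append(
            {
                "variable": var,
                f"{groups[0]}_mean_sd": f"{t2[0][0]}/{t2[0][1]}",
                f"{groups[1]}_mean_sd": f"{t2[1][0]}/{t2[1][1]}",
                "f_test_p": None,
                "t_test_p": None,
                "fisher_p": fisher_exact_2x2(t2),
                f"{groups[0]}_missing": int(g0[var].isna().sum()),
                f"{groups[1]}_missing": int(g1[var].isna().sum()),
            }
        )
    return table
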