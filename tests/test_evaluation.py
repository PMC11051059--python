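"""Exact CIs, DeLong AUC, cutoff optimization, and group-comparison tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecgedge.evaluation import (
    EvaluationError,
    auc_delong,
    clopper_pearson_ci,
    compare_groups,
    confusion_at_cutoff,
    fisher_exact_2x2,
    metrics_with_ci,
    optimize_cutoff,
    roc_points,
    variance_then_t_test,
)


def brute_force_auc(scores, labels):
    """Pair counting: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClopperPearson:
    def test_degenerate_bounds(self):
        lo, hi = clopper_pearson_ci(0, 10)
        assert lo == 0.0 and hi < 1.0
        lo, hi = clopper_pearson_ci(10, 10)
        assert lo > 0.0 and hi == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(EvaluationError):
            clopper_pearson_ci(5, 4)
        with pytest.raises(EvaluationError):
            clopper_pearson_ci(0, 0)

    def test_interval_contains_point_estimate(self):
        for k, n in [(1, 30), (15, 30), (29, 30)]:
            lo, hi = clopper_pearson_ci(k, n)
            assert lo <= k / n <= hi

    def test_coverage_simulation(self):
        """Exact intervals are conservative: coverage >= 94% over 2000
        simulated binomials (n=117, p=0.8)."""
        rng = np.random.default_rng(0)
        p, n = 0.8, 117
        ks = rng.binomial(n, p, size=2000)
        covered = 0
        cis = {k: clopper_pearson_ci(int(k), n) for k in np.unique(ks)}
        for k in ks:
            lo, hi = cis[int(k)]
            covered += lo <= p <= hi
        assert covered / 2000 >= 0.94


class TestMetricsWithCi:
    def test_perfect_separation(self):
        scores = np.array([0.1] * 5 + [0.9] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        rep = metrics_with_ci(scores, labels, cutoff=0.5)
        for m in (rep.sensitivity, rep.specificity, rep.precision, rep.accuracy):
            assert m.estimate == 1.0
        assert rep.auc.estimate == 1.0

    def test_constant_scores_above_cutoff(self):
        scores = np.full(10, 0.3)
        labels = np.array([0, 1] * 5)
        rep = metrics_with_ci(scores, labels, cutoff=0.5, with_auc=False)
        assert rep.sensitivity.estimate == 0.0
        assert rep.specificity.estimate == 1.0

    def test_cutoff_boundaries(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        assert metrics_with_ci(scores, labels, 0.0, with_auc=False).sensitivity.estimate == 1.0
        assert metrics_with_ci(scores, labels, 1.1, with_auc=False).specificity.estimate == 1.0

    def test_precision_missing_when_no_positive_predictions(self):
        rep = metrics_with_ci([0.1, 0.2], [0, 1], cutoff=0.9, with_auc=False)
        assert rep.precision is None

    def test_estimates_sit_inside_their_cis(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        rep = metrics_with_ci(scores, labels, cutoff=0.5)
        for m in (rep.sensitivity, rep.specificity, rep.accuracy, rep.auc):
            assert m.ci_lower <= m.estimate <= m.ci_upper

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            metrics_with_ci([0.5, 0.6], [1, 1], 0.5)


class TestDelongAuc:
    def test_perfect_separation(self):
        auc, lo, hi = auc_delong([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert hi == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        auc, lo, hi = auc_delong(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert lo < 0.5 < hi

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(8), 1)  # duplicates force tie handling
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        auc, _, _ = auc_delong(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        a1, lo1, hi1 = auc_delong(scores, labels)
        a2, lo2, hi2 = auc_delong(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert lo1 == pytest.approx(lo2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc_delong([0.1, 0.2], [1, 1])


class TestOptimizeCutoff:
    @staticmethod
    def brute_force(scores, labels):
        uniq = np.unique(scores)
        grid = (uniq[:-1] + uniq[1:]) / 2
        best = None
        for cut in grid:
            c = confusion_at_cutoff(scores, labels, cut)
            sens = c.tp / (c.tp + c.fn)
            spec = c.tn / (c.tn + c.fp)
            key = (abs(sens - spec), -(sens + spec - 1), cut)
            if best is None or key < best[0]:
                best = (key, cut)
        return best[1]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(6), 2)
        labels = rng.integers(0, 2, 6)
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert optimize_cutoff(scores, labels) == pytest.approx(
            self.brute_force(scores, labels)
        )

    def test_perfectly_separated_gap_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert optimize_cutoff(scores, labels) == pytest.approx(0.5)

    def test_balanced_symmetric_scores(self):
        scores = np.concatenate(
            [np.linspace(0.0, 0.6, 50), np.linspace(0.4, 1.0, 50)]
        )
        labels = np.array([0] * 50 + [1] * 50)
        cut = optimize_cutoff(scores, labels)
        c = confusion_at_cutoff(scores, labels, cut)
        assert c.tp / 50 == pytest.approx(c.tn / 50, abs=0.05)


class TestFisherExact:
    def test_identity_table(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_matches_enumeration_over_fixed_margins(self):
        """Point-probability two-sided p equals full table enumeration."""
        def enumerate_p(table):
            (a, b), (c, d) = table
            r1, r2 = a + b, c + d
            c1 = a + c
            n = r1 + r2

            def prob(x):
                return (
                    math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
                )

            p_obs = prob(a)
            return sum(
                prob(x)
                for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                if prob(x) <= p_obs * (1 + 1e-9)
            )

        for table in ([[3, 7], [5, 2]], [[2, 2], [2, 2]], [[8, 1], [2, 6]], [[0, 5], [4, 1]]):
            assert fisher_exact_2x2(table) == pytest.approx(enumerate_p(table), abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    def test_transpose_and_swap_invariance(self, cells):
        a, b, c, d = cells
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        t = [[a, b], [c, d]]
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestVarianceThenT:
    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        f_p, t_p = variance_then_t_test(x, x.copy())
        assert f_p == pytest.approx(1.0)
        assert t_p == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        _, t_p = variance_then_t_test(a, b)
        assert t_p < 1e-6

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 25)
        assert variance_then_t_test(a, b) == pytest.approx(variance_then_t_test(b, a))

    def test_degenerate_zero_variance(self):
        assert variance_then_t_test([1.0, 1.0], [1.0, 1.0]) == (None, None)

    def test_students_t_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        from scipy import stats

        expected = stats.ttest_ind(a, b, equal_var=True).pvalue
        _, t_p = variance_then_t_test(a, b)
        assert t_p == pytest.approx(expected)


class TestGroupComparison:
    def test_table_shape_and_missing_counts(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame(
            {
                "group": ["AF"] * n + ["nonAF"] * n,
                "age": rng.normal(70, 10, 2 * n),
                "diabetes": rng.integers(0, 2, 2 * n).astype(float),
            }
        )
        df.loc[3, "diabetes"] = np.nan
        table = compare_groups(df, "group", ["age"], ["diabetes"]).to_frame()
        assert len(table) == 2
        assert table.loc[0, "t_test_p"] is not None
        assert 0 <= table.loc[1, "fisher_p"] <= 1
        assert table.loc[1, "AF_missing"] == 1


class TestRocPoints:
    def test_monotone_curve(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = (scores > 0.4).astype(int)
        pts = roc_points(scores, labels)
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()
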