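"""Differential-expression screen: t-test, BH, fold change, AUC, Shapiro."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirblood.diffexp import (
    auc_two_group,
    bh_adjust,
    fold_change,
    rank_by_fold_change,
    run_diffexp,
    shapiro_median,
    ttest_two_group,
)
from tests.conftest import make_expression


class TestTTest:
    def test_no_effect_gives_t0_p1(self):
        t, p = ttest_two_group([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_textbook_pooled_variance_computation(self):
        """Independent closed-form oracle: pooled-variance t with 6 df."""
        x, y = np.array([1, 2, 3, 4.0]), np.array([3, 4, 5, 6.0])
        sp2 = (3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=6)
        t, p = ttest_two_group(x, y)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(p_expected)

    def test_group_swap_flips_t_keeps_p(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        t1, p1 = ttest_two_group(a, b)
        t2, p2 = ttest_two_group(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        t, p = ttest_two_group([2, 2], [1, 1])
        assert t == np.inf and p == 0.0

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 2"):
            ttest_two_group([1.0], [1, 2])


class TestBHAdjust:
    def test_single_test_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @staticmethod
    def _oracle(p):
        """Brute-force step-up: q_(i) = min_{j>=i} m*p_(j)/j, input order."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            q[order[rank - 1]] = min(running, 1.0)
        return q

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])


class TestFoldChange:
    @pytest.mark.parametrize(
        "ctrl, case, fc, direction",
        [
            (7.34, 6.57, 2.16, "down"),
            (12.67, 11.91, 2.14, "down"),
            (5.10, 5.40, 1.35, "up"),
            (7.15, 6.55, 1.82, "down"),
        ],
    )
    def test_exp_of_median_difference_reproduces_report_rows(self, ctrl, case, fc, direction):
        got_fc, got_dir = fold_change(ctrl, case)
        assert round(got_fc, 2) == fc and got_dir == direction

    def test_identity_and_symmetry(self):
        assert fold_change(3.3, 3.3)[0] == 1.0
        assert fold_change(2.0, 5.0)[0] == pytest.approx(fold_change(5.0, 2.0)[0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fold_change(np.nan, 1.0)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_two_group([4, 5, 6], [1, 2, 3]) == 1.0

    def test_identical_multisets_give_half(self):
        assert auc_two_group([1, 2, 2, 3], [1, 2, 2, 3]) == 0.5

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n1, n2 = rng.integers(1, 8, 2)
            a = rng.integers(0, 5, n1).astype(float)  # integer values force ties
            b = rng.integers(0, 5, n2).astype(float)
            wins = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
            u = wins / (n1 * n2)
            assert auc_two_group(a, b) == pytest.approx(max(u, 1 - u))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(1, 1, 15), rng.normal(0, 1, 20)
        assert auc_two_group(a, b) == pytest.approx(auc_two_group(np.exp(a), np.exp(b)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            auc_two_group([], [1.0])


class TestShapiroMedian:
    def test_normal_panel_median_near_half(self):
        rng = np.random.default_rng(7)
        expr = make_expression(rng.normal(0, 1, (100, 50)), ["case"] * 25 + ["control"] * 25)
        med, per = shapiro_median(expr)
        assert 0.3 <= med <= 0.7 and per.notna().all()

    def test_heavy_tailed_panel_median_tiny(self):
        rng = np.random.default_rng(8)
        expr = make_expression(np.exp(rng.normal(0, 2, (100, 50))), ["case"] * 25 + ["control"] * 25)
        med, _ = shapiro_median(expr)
        assert med < 0.01

    def test_single_feature_and_constant_policy(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 1, 30), np.full(30, 2.0)])
        expr = make_expression(x, ["case"] * 15 + ["control"] * 15)
        med, per = shapiro_median(expr)
        assert np.isnan(per.iloc[1]) and med == pytest.approx(per.iloc[0])


class TestRunDiffexp:
    def test_constant_matrix_nothing_significant(self):
        expr = make_expression(np.full((10, 12), 3.0), ["case"] * 6 + ["control"] * 6)
        tab = run_diffexp(expr)
        assert (~tab["significant"]).all()
        assert (tab["fold_change"] == 1.0).all()
        assert (tab["p_raw"] == 1.0).all()

    def test_one_class_partition_rejected(self):
        expr = make_expression(np.random.default_rng(0).normal(size=(5, 8)), ["case"] * 8)
        with pytest.raises(ValueError, match="2 classes"):
            run_diffexp(expr)

    def test_recovers_planted_effects_on_one_cohort(self, default_cohort, normalized_default):
        expr, _ = normalized_default
        tab = run_diffexp(expr)
        truth = default_cohort.truth
        sig = tab["significant"]
        planted = truth["is_differential"]
        sens = (sig & planted).sum() / planted.sum()
        fdp = (sig & ~planted).sum() / max(int(sig.sum()), 1)
        assert sens >= 0.8
        assert fdp <= 0.15  # single-cohort bound; the mean-FDR property is tested separately

    def test_direction_consistent_with_t_sign(self, normalized_default):
        """Where group means and medians order the same way, direction agrees
        with the sign of t (which is driven by the means)."""
        expr, _ = normalized_default
        tab = run_diffexp(expr)
        case = (expr.labels == "case").to_numpy()
        x = expr.values.to_numpy()
        mean_diff = x[:, case].mean(axis=1) - x[:, ~case].mean(axis=1)
        med_diff = (tab["median_case"] - tab["median_control"]).to_numpy()
        agree = (np.sign(mean_diff) == np.sign(med_diff)) & (med_diff != 0)
        up = (tab["direction"] == "up").to_numpy()
        assert ((tab["t_statistic"].to_numpy()[agree & up]) > 0).all()
        assert ((tab["t_statistic"].to_numpy()[agree & ~up]) < 0).all()

    def test_ranking_by_absolute_log_fold_change(self):
        rng = np.random.default_rng(10)
        expr = make_expression(rng.normal(0, 1, (20, 16)), ["case"] * 8 + ["control"] * 8)
        ranked = rank_by_fold_change(run_diffexp(expr))
        key = np.abs(np.log(ranked["fold_change"].to_numpy()))
        assert (np.diff(key) <= 1e-12).all()
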