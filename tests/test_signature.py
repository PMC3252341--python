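"""Signature cross-validation: filter selection, CV metrics, permutation null."""

import numpy as np
import pandas as pd
import pytest

from mirblood.signature import (
    CVConfig,
    cv_evaluate,
    filter_top_s,
    permutation_null,
    subset_sweep_summary,
)
from tests.conftest import make_expression

TINY = dict(kernels=("rbf",), costs=(1.0,), n_folds=5, n_repetitions=3)


def _labels(n_case, n_ctrl):
    return np.array(["case"] * n_case + ["control"] * n_ctrl)


def _random_expr(rng, p, n_case, n_ctrl):
    return make_expression(rng.normal(0, 1, (p, n_case + n_ctrl)), _labels(n_case, n_ctrl))


class TestFilterTopS:
    def test_full_subset_returns_all_ranked(self):
        rng = np.random.default_rng(0)
        expr = _random_expr(rng, 12, 10, 10)
        ids = filter_top_s(expr.values, expr.labels, 12)
        assert sorted(ids) == sorted(expr.values.index)

    def test_planted_feature_ranks_first_in_most_training_sets(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, (50, 40))
            x[7, :20] += 3.0  # 3-sd shift on feature 7
            expr = make_expression(x, _labels(20, 20))
            hits += filter_top_s(expr.values, expr.labels, 1)[0] == "f0007"
        assert hits >= 19

    def test_constant_data_tie_breaks_by_feature_id(self):
        expr = make_expression(np.full((6, 10), 1.0), _labels(5, 5))
        assert filter_top_s(expr.values, expr.labels, 6) == list(expr.values.index)

    def test_s_larger_than_panel_rejected(self):
        expr = make_expression(np.zeros((4, 10)), _labels(5, 5))
        with pytest.raises(ValueError, match="s must be"):
            filter_top_s(expr.values, expr.labels, 5)


class TestCVEvaluate:
    def test_single_perfectly_separating_feature_gives_near_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        x = np.zeros((1, 40))
        x[0, :20] = 10.0 + rng.normal(0, 0.01, 20)
        expr = make_expression(x, _labels(20, 20))
        res = cv_evaluate(expr, config=CVConfig(subset_sizes=(1,), seed=2, **TINY))
        assert res.summary["accuracy"].min() >= 0.99

    def test_null_data_stays_at_chance(self):
        rng = np.random.default_rng(2)
        expr = _random_expr(rng, 60, 30, 30)
        res = cv_evaluate(expr, config=CVConfig(subset_sizes=(10,), seed=3, **TINY),
                          compute_log_odds=False)
        acc = res.best["accuracy"]
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / 60)

    def test_class_swap_swaps_sensitivity_and_specificity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (20, 30))
        x[0, :12] += 1.5
        cfg = dict(kernels=("linear",), costs=(1.0,), n_folds=5, n_repetitions=2,
                   subset_sizes=(3,), stratified=False, seed=4)
        e1 = make_expression(x, np.array(["a"] * 12 + ["b"] * 18))
        e2 = make_expression(x, np.array(["b"] * 12 + ["a"] * 18))
        r1 = cv_evaluate(e1, config=CVConfig(**cfg), compute_log_odds=False)
        r2 = cv_evaluate(e2, config=CVConfig(**cfg), compute_log_odds=False)
        # unstratified folds depend only on n and seed, so the swap is exact
        assert r1.best["accuracy"] == pytest.approx(r2.best["accuracy"])
        assert r1.best["sensitivity"] == pytest.approx(r2.best["specificity"])
        assert r1.best["specificity"] == pytest.approx(r2.best["sensitivity"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        expr = _random_expr(rng, 30, 15, 15)
        cfg = CVConfig(subset_sizes=(5,), seed=5, **TINY)
        r1 = cv_evaluate(expr, config=cfg)
        r2 = cv_evaluate(expr, config=cfg)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        pd.testing.assert_series_equal(r1.log_odds, r2.log_odds)

    def test_log_odds_orientation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.1, (10, 30))
        x[0, :15] += 5.0
        expr = make_expression(x, _labels(15, 15))
        res = cv_evaluate(expr, config=CVConfig(subset_sizes=(1,), seed=6, **TINY))
        lo = res.log_odds
        assert np.isfinite(lo).all()
        assert lo.iloc[:15].mean() > 0 > lo.iloc[15:].mean()

    def test_fold_count_reduced_with_warning_for_tiny_class(self):
        rng = np.random.default_rng(6)
        expr = _random_expr(rng, 10, 4, 20)
        cfg = CVConfig(kernels=("rbf",), costs=(1.0,), n_folds=10, n_repetitions=1,
                       subset_sizes=(2,), seed=7)
        with pytest.warns(RuntimeWarning, match="folds"):
            res = cv_evaluate(expr, config=cfg, compute_log_odds=False)
        assert res.config.n_folds == 4


def test_per_fold_normalization_is_leakage_free_and_sane():
    """With normalize_per_fold, VSN is refit on each training fold and the
    held-out arrays are calibrated against the frozen training profile; a
    cohort with strong planted effects still classifies near-perfectly."""
    from mirblood.preprocess import summarize_replicates
    from mirblood.synthetic import SyntheticSpec, generate_cohort

    spec = SyntheticSpec(n_cases=12, n_controls=12, n_features=80, n_replicates=3,
                         n_differential=10, seed=17)
    raw = generate_cohort(spec)
    summ = summarize_replicates(raw)
    expr = make_expression(summ.values.to_numpy(), raw.labels.to_numpy())
    cfg = CVConfig(kernels=("rbf",), costs=(1.0,), n_folds=4, n_repetitions=2,
                   subset_sizes=(10,), normalize_per_fold=True, seed=18)
    with pytest.raises(ValueError, match="summarized"):
        cv_evaluate(expr, config=cfg, compute_log_odds=False)
    res = cv_evaluate(expr, config=cfg, compute_log_odds=False,
                      summarized=expr.values)
    assert res.best["accuracy"] >= 0.9


def test_no_leakage_canary():
    """A probe equal to the label + tiny noise is always selected on real
    labels; on permuted labels the held-out accuracy stays at chance, which
    rules out selection leakage from the test folds."""
    rng = np.random.default_rng(7)
    n = 40
    y = _labels(20, 20)
    x = rng.normal(0, 1, (25, n))
    x[0] = (y == "case") + rng.normal(0, 0.01, n)
    expr = make_expression(x, y)
    # canary always selected
    for seed in range(5):
        cols = rng.permutation(n)[:30]
        ids = filter_top_s(expr.values.iloc[:, cols], expr.labels.iloc[cols], 1)
        assert ids == ["f0000"]
    perm = rng.permutation(y)
    expr_perm = make_expression(x, perm)
    res = cv_evaluate(expr_perm, config=CVConfig(subset_sizes=(1, 5), seed=8, **TINY),
                      compute_log_odds=False)
    assert abs(res.best["accuracy"] - 0.5) <= 3 * np.sqrt(0.25 / n) + 0.05


class TestPermutationNull:
    def test_separable_data_beats_the_null(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.1, (15, 30))
        x[0, :15] += 5.0
        expr = make_expression(x, _labels(15, 15))
        cfg = CVConfig(kernels=("rbf",), costs=(1.0,), n_folds=5, n_repetitions=1,
                       subset_sizes=(2,), seed=9)
        res = permutation_null(expr, config=cfg, n_permutations=12)
        assert res.percentile > 95.0

    def test_null_data_sits_inside_the_null(self):
        rng = np.random.default_rng(9)
        expr = _random_expr(rng, 20, 15, 15)
        cfg = CVConfig(kernels=("rbf",), costs=(1.0,), n_folds=5, n_repetitions=1,
                       subset_sizes=(3,), seed=10)
        res = permutation_null(expr, config=cfg, n_permutations=12)
        assert 5.0 <= res.percentile <= 95.0

    def test_fixed_seed_reproduces_the_null_sample(self):
        rng = np.random.default_rng(10)
        expr = _random_expr(rng, 10, 8, 8)
        cfg = CVConfig(kernels=("linear",), costs=(1.0,), n_folds=4, n_repetitions=1,
                       subset_sizes=(2,), seed=11)
        r1 = permutation_null(expr, config=cfg, n_permutations=4)
        r2 = permutation_null(expr, config=cfg, n_permutations=4)
        assert np.array_equal(r1.null_accuracies, r2.null_accuracies)


class TestSubsetSweep:
    def test_single_subset_single_row_and_consistency(self):
        rng = np.random.default_rng(11)
        expr = _random_expr(rng, 10, 10, 10)
        res = cv_evaluate(expr, config=CVConfig(subset_sizes=(4,), seed=12, **TINY),
                          compute_log_odds=False)
        tab = subset_sweep_summary(res)
        assert len(tab) == 1 and bool(tab["best"].iloc[0])
        assert tab["accuracy"].iloc[0] == res.best["accuracy"]

    def test_accuracy_grows_with_subset_size_under_diluted_signal(self):
        """With 60 weakly informative probes, a subset of 60 beats a subset
        of 5: each probe alone is too weak, jointly they classify."""
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, (100, 60))
        x[:60, :30] += 0.5
        expr = make_expression(x, _labels(30, 30))
        cfg = CVConfig(kernels=("rbf",), costs=(1.0,), n_folds=5, n_repetitions=20,
                       subset_sizes=(5, 60), seed=13)
        res = cv_evaluate(expr, config=cfg, compute_log_odds=False)
        tab = res.summary.set_index("s")
        assert tab.loc[60, "accuracy"] >= tab.loc[5, "accuracy"]
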