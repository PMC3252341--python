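"""Differential-expression screening on the normalized expression matrix.

Per-probe two-group t-tests with Benjamini-Hochberg false-discovery-rate
control, exp-scale fold changes with an up/down direction, a Shapiro-Wilk
normality diagnostic for the panel, and rank-based per-probe ROC AUC.  The
same screen applies to the case/control contrast and to any binary subgroup
partition of the samples.

Fold-change convention: the normalized scale behaves like a natural log for
bright probes, so the reported fold change is exp(|median(case) -
median(control)|), always >= 1, with direction "up" when the case median is
larger.  AUC is orientation-folded to max(u, 1-u) so both up- and
down-regulated probes report AUC >= 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix
from .synthetic import CASE, CONTROL


def ttest_two_group(
    x_case: np.ndarray, x_control: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired two-tailed t-test (Student by default, Welch optional).

    Policy for degenerate input: if both groups have zero variance and equal
    means the result is (t=0, p=1); zero variance with unequal means yields
    (+-inf, 0).  Fewer than 2 values per group is an error.
    """
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    if x_case.size < 2 or x_control.size < 2:
        raise ValueError(
            f"need >= 2 values per group, got {x_case.size} case / {x_control.size} control"
        )
    if np.var(x_case) == 0 and np.var(x_control) == 0:
        if np.mean(x_case) == np.mean(x_control):
            return 0.0, 1.0
        return float(np.sign(np.mean(x_case) - np.mean(x_control)) * np.inf), 0.0
    t, p = stats.ttest_ind(x_case, x_control, equal_var=equal_var)
    return float(t), float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(median_control: float, median_case: float) -> tuple[float, str]:
    """Exp-scale fold change and direction from normalized group medians.

    fc = exp(|median_case - median_control|) >= 1; direction is "up" iff the
    case median is strictly larger.
    """
    if not (np.isfinite(median_control) and np.isfinite(median_case)):
        raise ValueError(
            f"medians must be finite, got control={median_control}, case={median_case}"
        )
    fc = float(np.exp(abs(median_case - median_control)))
    direction = "up" if median_case > median_control else "down"
    return fc, direction


def auc_two_group(x_case: np.ndarray, x_control: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC, orientation-folded to [0.5, 1].

    Ties count one half; invariant under strictly monotone transforms of the
    values.
    """
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    if x_case.size == 0 or x_control.size == 0:
        raise ValueError("both groups must be non-empty")
    u = stats.mannwhitneyu(x_case, x_control, alternative="two-sided").statistic
    auc = float(u) / (x_case.size * x_control.size)
    return max(auc, 1.0 - auc)


def shapiro_median(expr: ExpressionMatrix) -> tuple[float, pd.Series]:
    """Median Shapiro-Wilk p-value across probes (all samples pooled).

    Constant probes have no defined statistic; their p is recorded as NaN and
    excluded from the median.
    """
    x = expr.values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError(f"Shapiro-Wilk needs >= 3 samples, got {x.shape[1]}")
    pvals = np.full(x.shape[0], np.nan)
    for k in range(x.shape[0]):
        row = x[k]
        if np.ptp(row) > 0:
            pvals[k] = stats.shapiro(row).pvalue
    per_feature = pd.Series(pvals, index=expr.values.index, name="shapiro_p")
    return float(np.nanmedian(pvals)), per_feature


def _group_matrices(
    values: pd.DataFrame, partition: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    part = partition.reindex(values.columns)
    if part.isna().any():
        missing = list(part.index[part.isna()])
        raise ValueError(f"partition missing labels for samples: {missing}")
    classes = sorted(part.unique())
    if len(classes) != 2:
        raise ValueError(f"partition must have exactly 2 classes, got {classes}")
    # case/control naming wins when present; otherwise the second sorted class
    # plays the "case" role
    pos = CASE if CASE in classes else classes[1]
    case_mask = (part == pos).to_numpy()
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError("each class needs >= 2 samples")
    x = values.to_numpy(dtype=float)
    return x[:, case_mask], x[:, ~case_mask]


def matrix_ttest(
    values: pd.DataFrame, partition: pd.Series, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row two-group t-test; zero-variance policy as above."""
    xc, xn = _group_matrices(values, partition)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xc, xn, axis=1, equal_var=equal_var)
        degenerate = (np.var(xc, axis=1) == 0) & (np.var(xn, axis=1) == 0)
        same = degenerate & (np.mean(xc, axis=1) == np.mean(xn, axis=1))
        diff = degenerate & ~same
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
        t = np.where(diff, np.sign(np.mean(xc, axis=1) - np.mean(xn, axis=1)) * np.inf, t)
        p = np.where(diff, 0.0, p)
    return t, p


def run_diffexp(
    expr: ExpressionMatrix,
    partition: pd.Series | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full differential-expression table for a binary partition.

    One row per probe: group medians, fold change + direction, t statistic,
    raw and BH-adjusted p, orientation-folded AUC, and a significance flag at
    ``alpha`` on the adjusted p.  Rows are returned in input probe order; use
    :func:`rank_by_fold_change` for the report ordering.
    """
    if partition is None:
        if expr.labels is None:
            raise ValueError("no partition given and the matrix carries no labels")
        partition = expr.labels
    xc, xn = _group_matrices(expr.values, partition)
    t, p_raw = matrix_ttest(expr.values, partition, equal_var=equal_var)
    p_adj = bh_adjust(np.clip(p_raw, 0.0, 1.0))
    med_case = np.median(xc, axis=1)
    med_ctrl = np.median(xn, axis=1)
    fc = np.exp(np.abs(med_case - med_ctrl))
    direction = np.where(med_case > med_ctrl, "up", "down")
    n1, n2 = xc.shape[1], xn.shape[1]
    # rank-based AUC for all rows at once (ties get midranks)
    ranks = stats.rankdata(np.concatenate([xc, xn], axis=1), axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2
    auc = u / (n1 * n2)
    auc = np.maximum(auc, 1.0 - auc)
    return pd.DataFrame(
        {
            "median_control": med_ctrl,
            "median_case": med_case,
            "fold_change": fc,
            "direction": direction,
            "t_statistic": t,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "auc": auc,
            "significant": p_adj < alpha,
        },
        index=expr.values.index,
    )


def rank_by_fold_change(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by |ln fold change| descending, ties broken by probe id."""
    key = np.abs(np.log(table["fold_change"].to_numpy()))
    order = np.lexsort((table.index.to_numpy(), -key))
    return table.iloc[order]
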