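"""RT-qPCR comparative-Ct (2^-ddCt) validation analytics.

Replicate wells are averaged to one Ct per sample per miRNA; each target's
Ct is normalized against the endogenous reference (miR-16 by default) to a
per-sample delta-Ct; ddCt = mean dCt(case) - mean dCt(control) gives the
group fold change 2^-ddCt.  Because a *higher* dCt means *lower* expression,
the direction label is "up" when the case group's mean dCt is smaller.  For
matched pairs the per-pair 2^-ddCt folds are also computed; their geometric
mean coincides with the unpaired group fold whenever the pairing is
complete.  Group differences are tested by t-test on dCt (the log-scale
quantity); ROC/AUC uses -dCt as the score so that higher expression scores
higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ttest_two_group
from .synthetic import CASE, CONTROL, QPCRTable

#: replicate Ct spread (cycles) above which a sample/miRNA well set is flagged
DEFAULT_SPREAD_THRESHOLD = 1.0


def mean_ct(table: QPCRTable, spread_threshold: float = DEFAULT_SPREAD_THRESHOLD) -> pd.DataFrame:
    """Average replicate wells: one row per (sample, miRNA).

    Columns: group, pair_id, ct (arithmetic mean of replicates, cycles),
    n_replicates, spread (max - min), flagged (spread > threshold).
    """
    rec = table.records
    if rec.empty:
        raise ValueError("empty qPCR table")
    grp = rec.groupby(["sample_id", "mirna_id"], sort=False)
    out = grp.agg(
        group=("group", "first"),
        pair_id=("pair_id", "first"),
        ct=("ct", "mean"),
        n_replicates=("ct", "size"),
        spread=("ct", lambda v: float(np.ptp(v))),
    ).reset_index()
    out["flagged"] = out["spread"] > spread_threshold
    return out


def delta_ct(table: QPCRTable, target: str,
             spread_threshold: float = DEFAULT_SPREAD_THRESHOLD) -> pd.DataFrame:
    """Per-sample delta-Ct = mean Ct(target) - mean Ct(reference).

    Every sample measuring the target must also measure the reference;
    offenders are named in the error.
    """
    means = mean_ct(table, spread_threshold)
    tgt = means[means["mirna_id"] == target].set_index("sample_id")
    if tgt.empty:
        raise ValueError(f"target {target!r} not present in the table")
    ref = means[means["mirna_id"] == table.reference_mirna].set_index("sample_id")
    missing = [s for s in tgt.index if s not in ref.index]
    if missing:
        raise ValueError(
            f"samples missing reference {table.reference_mirna!r}: {missing}"
        )
    out = tgt[["group", "pair_id"]].copy()
    out["delta_ct"] = tgt["ct"] - ref.loc[tgt.index, "ct"]
    out["flagged"] = tgt["flagged"] | ref.loc[tgt.index, "flagged"].to_numpy()
    return out


@dataclass
class FoldChangeResult:
    ddct: float  # mean dCt(case) - mean dCt(control), cycles
    fold: float  # 2^-ddct
    magnitude: float  # max(fold, 1/fold), reported with a direction
    direction: str  # "up" iff case mean dCt < control mean dCt
    per_pair_folds: pd.Series | None = None
    geometric_mean_fold: float | None = None
    arithmetic_mean_fold: float | None = None


def relative_fold_change(
    dct_cases: pd.Series | np.ndarray,
    dct_controls: pd.Series | np.ndarray,
    paired: bool = False,
    pair_ids_cases: pd.Series | None = None,
    pair_ids_controls: pd.Series | None = None,
) -> FoldChangeResult:
    """Group (and optionally per-pair) 2^-ddCt fold change.

    Unpaired: ddCt from the group means.  Paired: per-pair folds
    2^-(dCt_case - dCt_control) aligned by pair id; their geometric mean
    equals the unpaired group fold when every pair is complete, and the
    arithmetic mean is reported separately (it differs under noise).
    """
    ca = np.asarray(dct_cases, dtype=float)
    co = np.asarray(dct_controls, dtype=float)
    if ca.size == 0 or co.size == 0:
        raise ValueError("both groups must be non-empty")
    ddct = float(ca.mean() - co.mean())
    fold = float(2.0 ** (-ddct))
    direction = "up" if ddct < 0 else "down"
    magnitude = max(fold, 1.0 / fold)
    res = FoldChangeResult(ddct=ddct, fold=fold, magnitude=magnitude, direction=direction)
    if paired:
        if pair_ids_cases is None or pair_ids_controls is None:
            raise ValueError("paired=True requires pair ids for both groups")
        case_by_pair = pd.Series(ca, index=pd.Index(pair_ids_cases))
        ctrl_by_pair = pd.Series(co, index=pd.Index(pair_ids_controls))
        if ca.size != co.size or sorted(case_by_pair.index) != sorted(ctrl_by_pair.index):
            raise ValueError("misaligned pairs: case and control pair ids differ")
        ctrl_by_pair = ctrl_by_pair.reindex(case_by_pair.index)
        per_pair = 2.0 ** (-(case_by_pair - ctrl_by_pair))
        per_pair.name = "fold"
        res.per_pair_folds = per_pair
        res.geometric_mean_fold = float(stats.gmean(per_pair))
        res.arithmetic_mean_fold = float(per_pair.mean())
    return res


@dataclass
class QPCRResult:
    target: str
    delta_ct_table: pd.DataFrame  # per-sample dCt with group/pair/flag
    fold: FoldChangeResult
    t_statistic: float
    p_value: float
    auc: float
    significant: bool
    alpha: float = 0.05


def qpcr_compare(
    table: QPCRTable,
    target: str,
    alpha: float = 0.05,
    equal_var: bool = True,
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
) -> QPCRResult:
    """Full validation comparison for one target miRNA.

    Per-sample dCt, two-tailed t-test between groups on dCt, group 2^-ddCt
    fold change (with per-pair folds when pair ids are present for all
    samples), and AUC with -dCt as the score.
    """
    dct = delta_ct(table, target, spread_threshold)
    groups = set(dct["group"])
    if not {CASE, CONTROL} <= groups:
        raise ValueError(f"target {target!r} needs both groups, found {sorted(groups)}")
    ca = dct[dct["group"] == CASE]
    co = dct[dct["group"] == CONTROL]
    paired = dct["pair_id"].notna().all() and len(ca) == len(co)
    fold = relative_fold_change(
        ca["delta_ct"], co["delta_ct"], paired=paired,
        pair_ids_cases=ca["pair_id"] if paired else None,
        pair_ids_controls=co["pair_id"] if paired else None,
    )
    t, p = ttest_two_group(ca["delta_ct"], co["delta_ct"], equal_var=equal_var)
    score_case = -ca["delta_ct"].to_numpy()
    score_ctrl = -co["delta_ct"].to_numpy()
    u = stats.mannwhitneyu(score_case, score_ctrl, alternative="two-sided").statistic
    auc = float(u) / (score_case.size * score_ctrl.size)
    return QPCRResult(
        target=target,
        delta_ct_table=dct,
        fold=fold,
        t_statistic=t,
        p_value=p,
        auc=auc,
        significant=p < alpha,
        alpha=alpha,
    )
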