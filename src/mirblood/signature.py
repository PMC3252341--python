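"""Multi-miRNA signature evaluation by filter-embedded SVM cross-validation.

Repeated stratified k-fold cross-validation where, inside every training
fold, probes are ranked by two-group t-test p-value and the top ``s`` are
used to train soft-margin SVMs over a kernel x cost grid.  Feature selection
happens strictly on the training portion, so the held-out estimates are free
of selection leakage.  Confusion counts are pooled across the folds of one
repetition; accuracy, sensitivity (case = positive) and specificity are
averaged over repetitions.  A label-permutation null re-runs the whole
procedure on shuffled labels to expose overtraining, and per-sample held-out
log-odds ln(P(case)/P(control)) are produced for the best configuration via
sigmoid-calibrated SVM probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import ExpressionMatrix
from .synthetic import CASE

_KERNELS = ("linear", "polynomial", "sigmoid", "rbf")
_SKLEARN_KERNEL = {"linear": "linear", "polynomial": "poly", "sigmoid": "sigmoid", "rbf": "rbf"}

_PROB_CLAMP = 1e-6


@dataclass
class CVConfig:
    """Grid and resampling settings for the signature evaluation.

    Defaults follow the discovery analysis: rbf kernel, costs 0.01-10 in
    decimal powers, 100 repetitions of stratified 10-fold CV, filter subset
    sizes 10, 20, ..., 300.
    """

    kernels: tuple[str, ...] = ("rbf",)
    costs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    n_folds: int = 10
    n_repetitions: int = 100
    subset_sizes: tuple[int, ...] = tuple(range(10, 301, 10))
    stratified: bool = True
    #: refit the variance-stabilizing normalization inside every training
    #: fold (leakage-free evaluation); requires passing the summarized
    #: matrix to cv_evaluate.  Off by default: the normalization is usually
    #: fitted once on the full matrix before CV.
    normalize_per_fold: bool = False
    seed: int = 0

    def validate(self, n_features: int, class_counts: dict) -> "CVConfig":
        bad = [k for k in self.kernels if k not in _KERNELS]
        if bad:
            raise ValueError(f"unknown kernels {bad}; choose from {_KERNELS}")
        if any(c <= 0 for c in self.costs):
            raise ValueError(f"costs must be > 0, got {self.costs}")
        if any(s < 1 or s > n_features for s in self.subset_sizes):
            raise ValueError(
                f"subset sizes must be in [1, {n_features}], got {self.subset_sizes}"
            )
        if self.n_repetitions < 1 or self.n_folds < 2:
            raise ValueError("need n_repetitions >= 1 and n_folds >= 2")
        n_min = min(class_counts.values())
        if self.n_folds > n_min:
            warnings.warn(
                f"n_folds={self.n_folds} exceeds smallest class ({n_min}); "
                f"using {n_min} folds instead",
                RuntimeWarning,
            )
            import dataclasses

            return dataclasses.replace(self, n_folds=n_min)
        return self


@dataclass
class SignatureCVResult:
    """Cross-validation summary over the (kernel, cost, subset size) grid."""

    summary: pd.DataFrame  # kernel, cost, s, accuracy/sensitivity/specificity mean+sd
    best: dict  # kernel, cost, s, accuracy
    log_odds: pd.Series | None = None  # per-sample held-out ln(P(case)/P(control))
    config: CVConfig | None = None
    per_repetition: pd.DataFrame | None = None  # long format, one row per rep x config


def filter_top_s(
    train_expr: pd.DataFrame, train_labels: pd.Series, s: int
) -> list[str]:
    """Top-``s`` probes by ascending training-set t-test p (ties by probe id).

    ``train_expr`` is probes x training samples.  The full ranked list is the
    s = n_features case.
    """
    n_features = train_expr.shape[0]
    if not 1 <= s <= n_features:
        raise ValueError(f"s must be in [1, {n_features}], got {s}")
    order = _filter_order(train_expr.to_numpy(dtype=float),
                          _case_mask(train_labels.reindex(train_expr.columns)))
    ranked = train_expr.index.to_numpy()[order]
    return list(ranked[:s])


def _case_mask(labels: pd.Series) -> np.ndarray:
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    pos = CASE if CASE in classes else classes[1]
    return (labels == pos).to_numpy()


def _filter_order(x: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """p-value ranking with deterministic id-order tie-break."""
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(x[:, case_mask], x[:, ~case_mask], axis=1)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance probes: p = 1 policy
    return np.lexsort((np.arange(x.shape[0]), p))


def _fold_iter(labels: np.ndarray, n_folds: int, stratified: bool, rng: np.random.Generator):
    """Yield (train_idx, test_idx); refolds up to 10x if a training side is one-class."""
    for _ in range(10):
        seed = int(rng.integers(0, 2**31 - 1))
        if stratified:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        else:
            from sklearn.model_selection import KFold

            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros(labels.size), labels))
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both classes in every training set")


def _make_svc(kernel: str, cost: float, probability: bool = False):
    svc = SVC(kernel=_SKLEARN_KERNEL[kernel], C=cost, gamma="scale", random_state=0)
    if probability:
        # Platt-style sigmoid calibration, fit on internal training-fold splits
        from sklearn.calibration import CalibratedClassifierCV

        svc = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    return make_pipeline(StandardScaler(), svc)


def _per_fold_normalize(summ_values: pd.DataFrame, tr: np.ndarray, te: np.ndarray):
    """Leakage-free normalization: fit VSN on the training arrays, calibrate
    each held-out array against the frozen training profile."""
    from .preprocess import (
        SummarizedMatrix,
        calibrate_single_array,
        fit_vsn,
        transform_vsn,
    )

    m_tr = SummarizedMatrix(values=summ_values.iloc[:, tr])
    params = fit_vsn(m_tr, max_iter=5)
    h_tr = transform_vsn(m_tr, params).values.to_numpy()
    mu = h_tr.mean(axis=1)
    a_med = float(params.params["a"].median())
    s_med = float(params.params["b"].median())
    h_te = np.empty((summ_values.shape[0], te.size))
    for j, col in enumerate(te):
        x = summ_values.iloc[:, col].to_numpy(dtype=float)
        a, s = calibrate_single_array(x, mu, a0=a_med, s0=s_med)
        h_te[:, j] = np.arcsinh((x - a) / s)
    return h_tr.T, h_te.T  # samples x features


def cv_evaluate(
    expr: ExpressionMatrix,
    labels: pd.Series | None = None,
    config: CVConfig | None = None,
    compute_log_odds: bool = True,
    summarized: pd.DataFrame | None = None,
) -> SignatureCVResult:
    """Repeated stratified k-fold CV over the kernel/cost/subset-size grid.

    Every repetition draws a fresh fold assignment from the seeded stream;
    every fold ranks probes on its training portion only and evaluates each
    (kernel, cost, s) cell on the held-out fold.  Confusion counts are pooled
    within a repetition; reported metrics are means (and sds) over
    repetitions.  When ``compute_log_odds`` is set, a second pass over the
    same fold assignments fits sigmoid-calibrated SVMs for the best cell and
    averages each sample's held-out log-odds over repetitions.
    """
    labels = expr.labels if labels is None else labels
    if labels is None:
        raise ValueError("labels required")
    labels = labels.reindex(expr.values.columns)
    y = _case_mask(labels)
    x = expr.values.to_numpy(dtype=float).T  # samples x features
    counts = {"pos": int(y.sum()), "neg": int((~y).sum())}
    if min(counts.values()) < 2:
        raise ValueError("both classes need >= 2 samples")
    config = (config or CVConfig()).validate(x.shape[1], counts)
    if config.normalize_per_fold and summarized is None:
        raise ValueError("normalize_per_fold requires the summarized matrix")

    def fold_data(tr, te):
        if config.normalize_per_fold:
            return _per_fold_normalize(summarized, tr, te)
        return x[tr], x[te]

    cells = [
        (k, c, s) for k in config.kernels for c in config.costs for s in config.subset_sizes
    ]
    rng = np.random.default_rng(config.seed)
    fold_seeds_rng = rng  # single stream; fold draws consume from it in order

    # confusion counts per cell per repetition
    rows = []
    fold_plans = []
    for rep in range(config.n_repetitions):
        folds = _fold_iter(y, config.n_folds, config.stratified, fold_seeds_rng)
        fold_plans.append(folds)
        conf = {cell: np.zeros(4, dtype=int) for cell in cells}  # tp, fn, tn, fp
        for tr, te in folds:
            x_tr, x_te = fold_data(tr, te)
            order = _filter_order(x_tr.T, y[tr])
            for kernel in config.kernels:
                for cost in config.costs:
                    for s in config.subset_sizes:
                        feats = order[:s]
                        clf = _make_svc(kernel, cost)
                        clf.fit(x_tr[:, feats], y[tr])
                        pred = clf.predict(x_te[:, feats])
                        truth = y[te]
                        tp = int(np.sum(pred & truth))
                        fn = int(np.sum(~pred & truth))
                        tn = int(np.sum(~pred & ~truth))
                        fp = int(np.sum(pred & ~truth))
                        conf[(kernel, cost, s)] += (tp, fn, tn, fp)
        for (kernel, cost, s), (tp, fn, tn, fp) in conf.items():
            rows.append(
                {
                    "repetition": rep,
                    "kernel": kernel,
                    "cost": cost,
                    "s": s,
                    "accuracy": (tp + tn) / (tp + fn + tn + fp),
                    "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                    "specificity": tn / (tn + fp) if tn + fp else np.nan,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby(["kernel", "cost", "s"], sort=False)
        .agg(
            accuracy=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            sensitivity=("sensitivity", "mean"),
            sensitivity_sd=("sensitivity", "std"),
            specificity=("specificity", "mean"),
            specificity_sd=("specificity", "std"),
        )
        .reset_index()
    )
    # best cell: highest mean accuracy; ties -> smaller s, then grid order
    best_row = summary.sort_values(
        ["accuracy", "s"], ascending=[False, True], kind="stable"
    ).iloc[0]
    best = {
        "kernel": best_row["kernel"],
        "cost": float(best_row["cost"]),
        "s": int(best_row["s"]),
        "accuracy": float(best_row["accuracy"]),
        "sensitivity": float(best_row["sensitivity"]),
        "specificity": float(best_row["specificity"]),
    }

    log_odds = None
    if compute_log_odds:
        sums = np.zeros(x.shape[0])
        counts_held = np.zeros(x.shape[0])
        for folds in fold_plans:
            for tr, te in folds:
                x_tr, x_te = fold_data(tr, te)
                order = _filter_order(x_tr.T, y[tr])
                feats = order[: best["s"]]
                clf = _make_svc(best["kernel"], best["cost"], probability=True)
                clf.fit(x_tr[:, feats], y[tr])
                prob = clf.predict_proba(x_te[:, feats])
                p_case = np.clip(prob[:, list(clf.classes_).index(True)],
                                 _PROB_CLAMP, 1 - _PROB_CLAMP)
                sums[te] += np.log(p_case / (1 - p_case))
                counts_held[te] += 1
        log_odds = pd.Series(sums / counts_held, index=expr.values.columns, name="log_odds")

    return SignatureCVResult(
        summary=summary, best=best, log_odds=log_odds, config=config, per_repetition=per_rep
    )


@dataclass
class PermutationNullResult:
    null_accuracies: np.ndarray
    real_accuracy: float
    percentile: float  # percentile of the real accuracy within the null


def permutation_null(
    expr: ExpressionMatrix,
    labels: pd.Series | None = None,
    config: CVConfig | None = None,
    n_permutations: int = 20,
) -> PermutationNullResult:
    """Label-permutation null for the best-cell accuracy (overtraining check).

    Each permutation shuffles the class labels once (seeded), reruns the full
    cross-validation, and records the best mean accuracy; the real accuracy's
    percentile within that null sample is reported.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    labels = expr.labels if labels is None else labels
    if labels is None:
        raise ValueError("labels required")
    labels = labels.reindex(expr.values.columns)
    config = config or CVConfig()
    real = cv_evaluate(expr, labels, config, compute_log_odds=False)
    rng = np.random.default_rng(config.seed + 1)
    null = []
    for i in range(n_permutations):
        perm = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index, name=labels.name
        )
        import dataclasses

        perm_config = dataclasses.replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        res = cv_evaluate(expr, perm, perm_config, compute_log_odds=False)
        null.append(res.best["accuracy"])
    null = np.asarray(null)
    percentile = float(stats.percentileofscore(null, real.best["accuracy"], kind="mean"))
    return PermutationNullResult(
        null_accuracies=null, real_accuracy=real.best["accuracy"], percentile=percentile
    )


def subset_sweep_summary(result: SignatureCVResult) -> pd.DataFrame:
    """Tidy s-vs-metrics table for plotting; flags the best cell."""
    tab = result.summary.copy()
    tab["best"] = [
        (row["kernel"], row["cost"], row["s"])
        == (result.best["kernel"], result.best["cost"], result.best["s"])
        for _, row in tab.iterrows()
    ]
    return tab
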