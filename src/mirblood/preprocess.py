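"""Replicate summarization and variance-stabilizing normalization.

Raw replicate-level intensities are reduced to one background-corrected
median per probe per array, then calibrated and transformed onto a
variance-stabilized, natural-log-like scale with the affine-arsinh
(generalized-log) transform

    h_i(x) = arsinh((x - a_i) / (lambda * b_i))

where (a_i, b_i) are per-array offset/gain calibration parameters and
``lambda`` is a single glog scale shared by all arrays.  Under the
multiplicative-additive error model  x = a + b*exp(mu + eta) + nu  the
transform with lambda ~ sd(nu)/sd(eta) makes the measurement variance
approximately independent of mean intensity; for bright probes
h ~ mu + eta + const, so group differences on this scale are natural-log
fold changes.

The calibration is estimated by trimmed profile likelihood: minimize

    (M/2) * log RSS  -  sum log h_i'(x)

where RSS is the sum of squared residuals of the transformed values around
per-probe row means, both sums running over the ``trim_fraction`` of probes
with the smallest residual sums (robustness against differential probes).
The log-Jacobian term is what pins down the overall scale and location; a
plain trimmed least squares would be degenerate (inflating b shrinks every
residual), and fixing a reference array to (a, b) = (0, 1) would bias the
variance stabilization whenever that array's true offset is nonzero.  All
2n parameters are therefore fitted freely; the reported ``ratio`` column
re-expresses the scales in the reference-array convention (first array = 1)
for calibration comparisons.  With noise present the likelihood identifies
the full parameter set; in the noise-free limit it is flat along the affine
reparameterization (a_i, b_i) -> (a_i + u*b_i, v*b_i), and only
gauge-invariant combinations are meaningful (see ``align_to_reference``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .synthetic import RawCohort


@dataclass
class SummarizedMatrix:
    """Background-corrected median intensities, probes x arrays."""

    values: pd.DataFrame  # index feature_id, columns sample_id

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CalibrationParams:
    """Fitted affine-arsinh calibration.

    ``params`` holds one row per array: offset ``a`` (intensity units), glog
    scale ``b`` (> 0, intensity units) used by the transform, and ``ratio``
    (scales re-expressed relative to the first array, reference-array
    convention).  ``lam`` is the fitted glog scale of the first array, i.e.
    the variance-stabilizing scale in reference-array units.
    """

    params: pd.DataFrame  # index sample_id, columns a, b, ratio
    lam: float
    iterations: int = 0
    trimmed_loss: float = float("nan")
    converged: bool = False

    def for_arrays(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        missing = [s for s in sample_ids if s not in self.params.index]
        if missing:
            raise KeyError(f"no calibration parameters for arrays: {missing}")
        sub = self.params.loc[list(sample_ids)]
        return sub["a"].to_numpy(), sub["b"].to_numpy()

    def align_to_reference(self, a_ref: float = 0.0, b_ref: float = 1.0) -> pd.DataFrame:
        """Re-express parameters in the gauge where array 1 is (a_ref, b_ref).

        The affine reparameterization (a_i, b_i) -> (a_i + u*b_i, v*b_i)
        leaves the consistency of the transformed arrays unchanged, so
        planted calibrations can only be compared in a common gauge.
        """
        a = self.params["a"].to_numpy()
        b = self.params["b"].to_numpy()
        v = b_ref / b[0]
        b_al = b * v
        a_al = a + (a_ref - a[0]) * (b / b[0])
        return pd.DataFrame({"a": a_al, "b": b_al}, index=self.params.index)


@dataclass
class ExpressionMatrix:
    """Normalized expression on the variance-stabilized scale."""

    values: pd.DataFrame  # index feature_id, columns sample_id
    labels: pd.Series | None = None  # index sample_id, values case/control
    provenance: dict = field(default_factory=dict)


def summarize_replicates(raw: RawCohort) -> SummarizedMatrix:
    """Median over replicate spots, then per-array background subtraction.

    The median is shift-equivariant, so subtracting the constant background
    from the median equals subtracting it from each replicate first.  Probes
    with missing (NaN) replicates are rejected by id — no silent imputation.
    """
    x = np.asarray(raw.intensities, dtype=float)
    if x.ndim != 3 or x.shape[2] < 1:
        raise ValueError("intensities must be (samples, features, replicates) with >=1 replicate")
    bad = np.isnan(x).any(axis=(0, 2))
    if bad.any():
        ids = [raw.feature_ids[k] for k in np.flatnonzero(bad)]
        raise ValueError(f"missing replicate intensities for features: {ids}")
    med = np.median(x, axis=2) - raw.background  # samples x features
    values = pd.DataFrame(
        med.T, index=pd.Index(raw.feature_ids, name="feature_id"), columns=raw.sample_ids
    )
    return SummarizedMatrix(values=values)


def _unpack(theta, n, a_unit):
    """theta = [a_1..a_n (in a_unit units), log s_1..log s_n]."""
    a = theta[:n] * a_unit
    s = np.exp(theta[n:])
    return a, s


def _objective(theta, x, n_arrays, a_unit):
    """Profile negative log-likelihood and its gradient.

    All 2n parameters are free: the log-Jacobian term identifies both the
    offsets and the glog scales (no reference-array gauge is needed, and
    fixing one would bias the variance stabilization whenever the reference
    array has a nonzero true offset).  Offsets are optimized in units of
    ``a_unit`` (the initial glog scale) so all coordinates are comparably
    scaled for L-BFGS-B.  x is features x arrays (kept features only).
    Residuals are around per-feature row means; the gradient contribution
    through the means vanishes because residuals sum to zero per row.
    """
    n = n_arrays
    a, s = _unpack(theta, n, a_unit)

    xa = x - a[None, :]
    q = np.sqrt(s[None, :] ** 2 + xa**2)
    h = np.arcsinh(xa / s[None, :])
    e = h - h.mean(axis=1, keepdims=True)
    m = e.size
    # tiny ridge keeps the objective finite when the data fit exactly
    rss = float(np.sum(e * e)) + 1e-12 * m
    f = 0.5 * m * np.log(rss) + np.sum(np.log(q))

    # dh/da = -1/q ; dh/ds = -xa/(s*q) ; dlog q/da = -xa/q^2 ; dlog q/ds = s/q^2
    w = m / rss
    grad_a = w * np.sum(e * (-1.0 / q), axis=0) + np.sum(-xa / (q * q), axis=0)
    dF_ds = w * np.sum(e * (-xa / (s[None, :] * q)), axis=0) + np.sum(
        s[None, :] / (q * q), axis=0
    )
    grad = np.concatenate([grad_a * a_unit, s * dF_ds])
    return f, grad


def fit_vsn(
    m: SummarizedMatrix,
    trim_fraction: float = 0.9,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> CalibrationParams:
    """Fit per-array affine-arsinh calibration by trimmed profile likelihood.

    Alternates (least-trimmed-squares style) between optimizing the
    parameters on the currently kept probes and re-selecting the
    ``trim_fraction`` of probes with smallest residual sums.  Deterministic
    given inputs and settings.  Non-convergence after ``max_iter`` sweeps
    emits a warning and returns the best parameters found.
    """
    x_df = m.values
    x = x_df.to_numpy(dtype=float)
    n_feat, n_arr = x.shape
    if n_arr < 2:
        raise ValueError(f"fit_vsn needs >= 2 arrays, got {n_arr}")
    if not 0 < trim_fraction <= 1:
        raise ValueError(f"trim_fraction must be in (0, 1], got {trim_fraction}")
    n_keep = max(2, int(round(trim_fraction * n_feat)))

    # Robust moment init: gain ratios from spread, offsets from the dim tail
    # (the affine offset sits just below the dimmest probes), glog scale from
    # the spread of the dimmest probes of the first array.
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med[None, :]), axis=0)
    mad = np.where(mad <= 0, 1.0, mad)
    b0 = mad / mad[0]
    a0 = np.quantile(x, 0.02, axis=0)
    low = x[:, 0][x[:, 0] <= np.quantile(x[:, 0], 0.1)]
    lam0 = float(np.std(low)) if low.size > 1 and np.std(low) > 0 else 1.0
    a_unit = lam0
    s0 = lam0 * b0
    theta = np.concatenate([a0 / a_unit, np.log(s0)])
    # loose box constraints keep the line search away from degenerate scales
    a_lo = (x.min(axis=0) - 20.0 * lam0) / a_unit
    a_hi = np.quantile(x, 0.75, axis=0) / a_unit
    bounds = [(a_lo[i], a_hi[i]) for i in range(n_arr)] + [
        (np.log(s0[i]) - np.log(1e4), np.log(s0[i]) + np.log(1e4)) for i in range(n_arr)
    ]

    converged = False
    loss = float("nan")
    it = 0
    with np.errstate(over="ignore", invalid="ignore"):
        # Pilot fit on all probes: anchors the glog scale before trimming
        # (trimming from a poor start can discard the dim probes that pin
        # down the scale and let it run away).
        res = minimize(
            _objective,
            theta,
            args=(x, n_arr, a_unit),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        keep = _kept_features(theta, x, n_arr, n_keep, a_unit)
        for it in range(1, max_iter + 1):
            res = minimize(
                _objective,
                theta,
                args=(x[keep], n_arr, a_unit),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
            )
            step = float(np.max(np.abs(res.x - theta)))
            theta = res.x
            loss = float(res.fun)
            new_keep = _kept_features(theta, x, n_arr, n_keep, a_unit)
            same = np.array_equal(new_keep, keep)
            keep = new_keep
            if same and step < tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"VSN calibration did not converge after {max_iter} sweeps "
            f"(last step {step:.2e}); returning best-so-far parameters.",
            RuntimeWarning,
        )

    a, s = _unpack(theta, n_arr, a_unit)
    lam = float(s[0])
    params = pd.DataFrame(
        {"a": a, "b": s, "ratio": s / s[0]},
        index=pd.Index(x_df.columns, name="sample_id"),
    )
    return CalibrationParams(
        params=params, lam=lam, iterations=it, trimmed_loss=loss, converged=converged
    )


def _kept_features(theta, x, n_arr, n_keep, a_unit):
    a, s = _unpack(theta, n_arr, a_unit)
    h = np.arcsinh((x - a[None, :]) / s[None, :])
    e = h - h.mean(axis=1, keepdims=True)
    rs = np.sum(e * e, axis=1)
    order = np.argsort(rs, kind="stable")
    return np.sort(order[:n_keep])


def transform_vsn(
    m: SummarizedMatrix,
    p: CalibrationParams,
    labels: pd.Series | None = None,
) -> ExpressionMatrix:
    """Apply the fitted calibration: value = arsinh((x - a_i) / b_i).

    Strictly increasing in raw intensity for each array; defined on all reals
    (negative background-corrected intensities are not clipped).
    """
    a, b = p.for_arrays(m.sample_ids)
    h = np.arcsinh((m.values.to_numpy(dtype=float) - a[None, :]) / b[None, :])
    values = pd.DataFrame(h, index=m.values.index, columns=m.values.columns)
    prov = {"lam": p.lam, "iterations": p.iterations, "converged": p.converged}
    return ExpressionMatrix(values=values, labels=labels, provenance=prov)


def calibrate_single_array(
    x: np.ndarray, reference_profile: np.ndarray, a0: float | None = None,
    s0: float | None = None,
) -> tuple[float, float]:
    """Fit one new array's (a, b) against a frozen reference profile.

    Used for leakage-free evaluation: the reference profile is the
    per-probe mean of already-normalized training arrays, and the new
    (held-out) array is calibrated to it without touching the training fit.
    Same objective as :func:`fit_vsn`, restricted to two parameters.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(reference_profile, dtype=float)
    if a0 is None:
        a0 = float(np.quantile(x, 0.02))
    if s0 is None or s0 <= 0:
        low = x[x <= np.quantile(x, 0.1)]
        s0 = float(np.std(low)) if low.size > 1 and np.std(low) > 0 else 1.0

    def nll(theta):
        a, s = theta[0], np.exp(theta[1])
        xa = x - a
        h = np.arcsinh(xa / s)
        rss = float(np.sum((h - mu) ** 2)) + 1e-12 * x.size
        return 0.5 * x.size * np.log(rss) + 0.5 * float(np.sum(np.log(s * s + xa * xa)))

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(nll, np.array([a0, np.log(s0)]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    return float(res.x[0]), float(np.exp(res.x[1]))


def normalize_cohort(
    raw: RawCohort,
    trim_fraction: float = 0.9,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> tuple[ExpressionMatrix, CalibrationParams]:
    """Convenience: summarize, fit, transform in one call."""
    summ = summarize_replicates(raw)
    params = fit_vsn(summ, trim_fraction=trim_fraction, max_iter=max_iter, tol=tol)
    expr = transform_vsn(summ, params, labels=raw.labels)
    return expr, params
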