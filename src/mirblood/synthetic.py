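"""Synthetic case-control cohorts for whole-blood miRNA profiling.

The generator emulates a two-color-free microarray experiment in which each
array (one per blood sample) carries ``n_replicates`` spots for each of
``n_features`` miRNA probes.  Spot intensities follow the
multiplicative-additive error model that underlies variance-stabilizing
normalization:

    x[i, k, r] = a_i + b_i * exp(mu_k + delta_k * 1[case] + eta[i, k])
                 + nu[i, k, r] + background

where ``mu_k`` is the latent log-abundance of probe ``k``, ``delta_k`` a
planted differential shift (zero for null probes), ``eta`` log-scale
biological/hybridization noise shared by the replicate spots of a probe, and
``nu`` additive spot-level read noise.  ``a_i`` (offset) and ``b_i`` (gain)
are per-array calibration parameters.  A parallel generator produces
long-format RT-qPCR Ct tables for matched case-control pairs.

Ground truth (which probes are differential, direction, effect size, and the
planted calibration) is carried on the returned cohort so downstream stages
can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

#: default number of up-regulated planted effects out of 59 differential probes
_DEFAULT_UP_FRACTION = 13 / 59


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic microarray cohort.

    Defaults reproduce the study conditions of an early-stage breast-cancer
    discovery cohort: 48 cases vs 57 controls measured on a 1100-probe panel
    with 7 replicate spots per probe, 59 differential probes (13 up, 46 down)
    with natural-log effect sizes spanning the fold-change range 1.35-3.12.
    """

    n_cases: int = 48
    n_controls: int = 57
    n_features: int = 1100
    n_replicates: int = 7
    n_differential: int = 59
    n_up: int | None = None  # default: round(n_differential * 13/59)
    effect_low: float = float(np.log(1.35))
    effect_high: float = float(np.log(3.12))
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    noise_multiplicative_sd: float = 0.25
    noise_additive_sd: float = 20.0
    array_offset_range: tuple[float, float] = (50.0, 200.0)
    array_scale_range: tuple[float, float] = (0.8, 1.25)
    #: explicit per-array calibration; overrides the uniform ranges when given
    array_offsets: Sequence[float] | None = None
    array_scales: Sequence[float] | None = None
    background: float = 30.0
    seed: int = 0

    def resolved_n_up(self) -> int:
        if self.n_up is not None:
            return self.n_up
        return int(round(self.n_differential * _DEFAULT_UP_FRACTION))

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_features", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 <= self.n_differential <= self.n_features:
            raise ValueError(
                f"n_differential must be in [0, n_features], got {self.n_differential}"
            )
        if not 0 <= self.resolved_n_up() <= self.n_differential:
            raise ValueError(f"n_up must be in [0, n_differential], got {self.n_up}")
        if self.n_differential > 0 and not 0 < self.effect_low <= self.effect_high:
            raise ValueError(
                "effect sizes must satisfy 0 < effect_low <= effect_high, got "
                f"effect_low={self.effect_low}, effect_high={self.effect_high}"
            )
        for name in ("baseline_sd", "noise_multiplicative_sd", "noise_additive_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.array_scales is not None and np.any(np.asarray(self.array_scales) <= 0):
            raise ValueError("array_scales must be > 0")
        if self.array_scale_range[0] <= 0:
            raise ValueError(f"array_scale_range must be > 0, got {self.array_scale_range}")
        for name in ("array_offsets", "array_scales"):
            vals = getattr(self, name)
            if vals is not None and len(vals) != self.n_samples:
                raise ValueError(
                    f"{name} must have one entry per sample "
                    f"({self.n_samples}), got {len(vals)}"
                )
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")


@dataclass
class RawCohort:
    """Replicate-level intensity tensor with labels and (optional) truth.

    ``intensities`` has shape (n_samples, n_features, n_replicates) in
    arbitrary fluorescence units; ``truth`` is present iff the cohort is
    synthetic and records, per feature, whether it is differential, its
    direction and signed natural-log effect size, plus the planted per-array
    calibration used downstream for normalization-recovery checks.
    """

    intensities: np.ndarray
    background: float
    labels: pd.Series  # index sample_id, values case/control
    sample_ids: list[str]
    feature_ids: list[str]
    truth: pd.DataFrame | None = None
    array_offsets: np.ndarray | None = None
    array_scales: np.ndarray | None = None
    spec: SyntheticSpec | None = None

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]


def generate_cohort(spec: SyntheticSpec) -> RawCohort:
    """Draw one replicate-level cohort from the generative model.

    Deterministic given ``spec`` (including its seed): the same spec yields
    bit-identical tensors.  Differential probes receive a latent mean shift of
    +effect (up) or -effect (down) in the case group; effects are drawn
    uniformly from [effect_low, effect_high].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, r = spec.n_samples, spec.n_features, spec.n_replicates

    sample_ids = [f"case_{i + 1:03d}" for i in range(spec.n_cases)] + [
        f"ctrl_{i + 1:03d}" for i in range(spec.n_controls)
    ]
    feature_ids = [f"miR-sim-{k + 1:04d}" for k in range(p)]
    labels = pd.Series(
        [CASE] * spec.n_cases + [CONTROL] * spec.n_controls,
        index=pd.Index(sample_ids, name="sample_id"),
        name="group",
    )
    is_case = (labels == CASE).to_numpy()

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=p)
    delta = np.zeros(p)
    diff_idx = rng.choice(p, size=spec.n_differential, replace=False)
    n_up = spec.resolved_n_up()
    effects = rng.uniform(spec.effect_low, spec.effect_high, size=spec.n_differential)
    signs = np.concatenate([np.ones(n_up), -np.ones(spec.n_differential - n_up)])
    delta[diff_idx] = signs * effects

    if spec.array_offsets is not None:
        a = np.asarray(spec.array_offsets, dtype=float)
    else:
        a = rng.uniform(*spec.array_offset_range, size=n)
    if spec.array_scales is not None:
        b = np.asarray(spec.array_scales, dtype=float)
    else:
        b = rng.uniform(*spec.array_scale_range, size=n)

    latent = mu[None, :] + delta[None, :] * is_case[:, None]
    eta = rng.normal(0.0, spec.noise_multiplicative_sd, size=(n, p))
    signal = a[:, None] + b[:, None] * np.exp(latent + eta)
    nu = rng.normal(0.0, spec.noise_additive_sd, size=(n, p, r))
    intensities = np.clip(signal[:, :, None] + nu + spec.background, 0.0, None)

    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", ""))
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "is_differential": delta != 0,
            "direction": direction,
            "effect": delta,
        }
    ).set_index("feature_id")

    return RawCohort(
        intensities=intensities,
        background=spec.background,
        labels=labels,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        truth=truth,
        array_offsets=a,
        array_scales=b,
        spec=spec,
    )


@dataclass
class QPCRTable:
    """Long-format qPCR Ct records plus the designated endogenous reference."""

    records: pd.DataFrame  # sample_id, group, pair_id, mirna_id, replicate, ct
    reference_mirna: str = "miR-16"

    def targets(self) -> list[str]:
        ids = self.records["mirna_id"].unique().tolist()
        return [m for m in ids if m != self.reference_mirna]


def generate_qpcr_cohort(
    n_pairs: int,
    true_log2_fold: Mapping[str, float] | float,
    ct_noise_sd: float = 0.25,
    seed: int = 0,
    reference_mirna: str = "miR-16",
    n_replicates: int = 2,
    reference_ct_mean: float = 20.0,
    base_delta_ct: float = 5.0,
    pair_sd: float = 0.5,
) -> QPCRTable:
    """Simulate a matched-pair RT-qPCR validation cohort.

    Each of ``n_pairs`` age-matched pairs contributes one case and one control
    sample; every sample measures every target plus the endogenous reference
    in ``n_replicates`` duplicate wells.  A target with ``true_log2_fold`` f
    has case delta-Ct shifted by -f cycles relative to its matched control
    (one cycle = one doubling), so 2^-ddCt recovers 2^f.  ``pair_sd`` is
    between-pair biological variation of the target baseline; ``ct_noise_sd``
    is per-well technical noise.
    """
    if n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {n_pairs}")
    if ct_noise_sd < 0:
        raise ValueError(f"ct_noise_sd must be >= 0, got {ct_noise_sd}")
    if isinstance(true_log2_fold, (int, float)):
        true_log2_fold = {"miR-target": float(true_log2_fold)}

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for pair in range(1, n_pairs + 1):
        pair_id = f"pair_{pair:02d}"
        base = {m: base_delta_ct + rng.normal(0.0, pair_sd) for m in true_log2_fold}
        for group in (CASE, CONTROL):
            sample_id = f"{'bc' if group == CASE else 'hc'}_{pair:02d}"
            ref_ct = reference_ct_mean + rng.normal(0.0, pair_sd)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "pair_id": pair_id,
                        "mirna_id": reference_mirna,
                        "replicate": rep,
                        "ct": ref_ct + rng.normal(0.0, ct_noise_sd),
                    }
                )
            for mirna, f in true_log2_fold.items():
                dct = base[mirna] - (f if group == CASE else 0.0)
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "pair_id": pair_id,
                            "mirna_id": mirna,
                            "replicate": rep,
                            "ct": ref_ct + dct + rng.normal(0.0, ct_noise_sd),
                        }
                    )
    return QPCRTable(records=pd.DataFrame(rows), reference_mirna=reference_mirna)
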