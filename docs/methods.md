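# Methods

## Generative model of the synthetic cohorts

The microarray generator draws spot-level intensities from the
multiplicative–additive error model that variance-stabilizing normalization
assumes:

    x[i,k,r] = a_i + b_i · exp(μ_k + δ_k·1[case i] + η[i,k]) + ν[i,k,r] + B

for array (sample) `i`, probe `k`, replicate spot `r`, with

| parameter | meaning | default | rationale |
|---|---|---|---|
| n_cases / n_controls | cohort sizes | 48 / 57 | discovery-cohort design |
| n_features | panel size (miRNAs + star sequences) | 1100 | panel design |
| n_replicates | replicate spots summarized per probe | 7 | summarization design; the physical array's 11 spots are available via config |
| n_differential, split | planted effects | 59 (13 up / 46 down) | discovery-result design |
| effect sizes \|δ\| | natural-log case shifts | Uniform[ln 1.35, ln 3.12] | span of the reported fold-change range |
| μ_k | latent log-abundance | Normal(7, 2) | places most probes well above background with a realistic dim tail |
| η | log-scale (multiplicative) noise, shared by a probe's spots | sd 0.25 | typical array CV ≈ 25% |
| ν | additive spot noise (intensity units) | sd 20 | comparable to background level |
| a_i, b_i | per-array affine calibration | U[50, 200], U[0.8, 1.25] | modest array-to-array drift |
| B | constant background | 30 | subtracted during summarization |

One seeded PRNG stream generates everything; identical spec + seed is
bit-identical. Intensities are clipped at zero (a negative draw is a ≈ 4σ
event at the defaults). Effects are planted on probes chosen uniformly at
random, so some land on dim probes — see *Limitations*.

The qPCR generator emulates a matched-pair validation cohort: per pair, a
shared target baseline (between-pair sd 0.5 cycles), a per-sample reference
Ct, duplicate wells with technical noise (default sd 0.25 cycles), and a
planted log2 fold that shifts the case ΔCt by −log2-fold cycles. The 2^−ΔΔCt
estimator recovers the planted fold with only the usual Jensen-type bias
(≈ e^{(ln2·σ_ΔΔCt)²/2}, negligible at these noise levels).

What the generator does **not** emulate: probe-sequence and GC effects,
cross-hybridization, spatial artifacts, batch structure, hemolysis and
cellularity differences, or amplification-efficiency deviations from 2.0 in
qPCR. Passing tests therefore demonstrate correctness of the analysis chain
under its own model assumptions, not robustness to those real-data
nuisances. Notably, the planted effects (Cohen's d ≈ 1.2–4.5 at η = 0.25)
make the synthetic cohorts far more classifiable than real whole-blood
cohorts; classifier checks are therefore sanity properties (separable ⇒
near-perfect, null ⇒ chance, permutation ⇒ real signal above the null), not
a reproduction of any particular accuracy figure.

## Summarization

Per probe per array: median over replicate spots, then subtraction of the
per-array constant background. The median is shift-equivariant, so the order
(background first or last) is immaterial. Whether the original platform used
a per-spot local background or a per-array constant is not knowable from the
summary level we model; a constant is used and configurable. Missing
replicates raise an error naming the probes — no silent imputation.

## Variance-stabilizing normalization

Transform family: `h_i(x) = arsinh((x − a_i)/b_i)`, strictly increasing,
defined on all reals (negative background-corrected values are not clipped),
`≈ ln(2(x − a_i)/b_i)` for bright probes and linear near the offset.

**Estimator.** Trimmed profile likelihood. With residuals `e` of the
transformed values around per-probe row means and `M` retained entries,
minimize

    F(a, b) = (M/2)·log RSS − Σ log h_i'(x)      h_i'(x) = 1/sqrt(b_i² + (x−a_i)²)

over all 2n parameters, keeping the `trim_fraction` (default 0.9) of probes
with the smallest residual sums so that differential probes do not distort
the calibration. The log-Jacobian term is essential: plain least squares is
degenerate (inflating every `b_i` shrinks all residuals toward zero), and it
is also what identifies the offsets and the absolute glog scale — at the
optimum `b_i ≈ calibration gain × σ_ν/σ_η`, which is exactly the scale that
makes `Var(h)` independent of intensity under the error model.

**Numerical scheme.**
- Robust moment initialization: gain ratios from column MADs, offsets from
  the 2% quantile, glog scale from the spread of the dimmest decile of the
  first array.
- An untrimmed pilot optimization precedes the trimming sweeps. Trimming
  from a poor start can discard the dim probes that pin down the glog scale,
  letting the scale run away; the pilot anchors it.
- Alternation: L-BFGS-B on all parameters (analytic gradient; offsets
  rescaled to glog-scale units so coordinates are comparable; loose box
  bounds keep line searches away from degenerate scales) alternating with
  re-selection of the kept probe set, up to `max_iter` sweeps (default 20),
  declared converged when the kept set is stable and the parameter step is
  below `tol` (default 1e-4). Non-convergence warns and returns best-so-far.
- A tiny ridge (1e-12·M) inside `log RSS` keeps the objective finite when
  the data fit exactly.

**Identifiability and gauge.** The reparameterization
`(a_i, b_i) → (a_i + u·b_i, v·b_i)` (common `u, v`) leaves the transformed
arrays' mutual consistency unchanged. With noise, the Jacobian term breaks
this freedom and the full parameter set is identified — fixing a reference
array to `(0, 1)` instead would *bias* the fit whenever that array's true
offset is nonzero, so no gauge constraint is imposed. In the noise-free
limit the likelihood is flat along the family, so parameter-recovery checks
compare gauge-aligned parameters (`CalibrationParams.align_to_reference`);
the reported `ratio` column gives scales in the reference-array convention.

On default synthetic cohorts the fitted transform holds the per-probe
residual sd within a few percent across intensity deciles (ratio ≈ 1.01 on
null probes) and recovers planted calibrations to ~1e-14 (noise-free,
gauge-aligned) or a few intensity units (full noise).

Normalization is fitted once on the full matrix, before cross-validation,
matching common practice for this design. For fully leakage-free evaluation,
`CVConfig(normalize_per_fold=True)` refits the calibration on each training
fold and calibrates every held-out array against the frozen training profile
(`calibrate_single_array`); it is off by default and costs one VSN fit per
fold.

## Differential expression

- **Test**: unpaired two-tailed t-test, Student (pooled variance) by
  default with a Welch option. Zero-variance probes are never dropped: equal
  means give `(t, p) = (0, 1)`, unequal means `(±∞, 0)`.
- **Multiplicity**: Benjamini–Hochberg step-up on the raw p-values;
  significance is `p_adjusted < α` (default 0.05). Backed by
  `statsmodels.multipletests` and pinned against a brute-force step-up
  oracle in the tests.
- **Fold change**: `exp(|median_case − median_control|)` with direction
  "up" iff the case median is strictly larger. The normalized scale is
  natural-log-like for bright probes, so this is the exp-scale fold; ranking
  tables sort by |ln fc| with ties broken by probe id.
- **AUC**: Mann–Whitney U/(n₁n₂) with midrank ties, folded to
  `max(u, 1−u)` so both up- and down-regulated probes report ≥ 0.5.
- **Normality diagnostic**: per-probe Shapiro–Wilk over all samples pooled;
  the median p across probes is reported; constant probes are excluded
  (recorded as missing).

At the default study conditions the screen's empirical FDR averages ≈ 0.046
over 50 cohorts — close to the Benjamini–Hochberg ceiling π₀·α ≈ 0.047 — with
sensitivity ≈ 0.99 for effects of at least 2-fold. (These figures are what
`scripts/acceptance.py` and the acceptance tests recompute.)

## Signature cross-validation

- Grid: kernels ⊆ {linear, polynomial, sigmoid, rbf} (default rbf), costs
  {0.01, 0.1, 1, 10} — "0.01 to 10 in decimal powers" — subset sizes 10…300
  by 10, 10-fold stratified CV, 100 repetitions (all configurable; the
  analysis drivers and the smoke tests use 10 repetitions and a short
  subset list).
- Folds are stratified because a 48/57 imbalance occasionally produces
  one-class training folds otherwise; a degenerate fold triggers refolding
  (up to 10 attempts). If the fold count exceeds the smallest class it is
  reduced with a warning.
- Inside each training fold only: probes ranked by raw t-test p (ties by
  probe id, zero-variance probes at p = 1), top *s* kept, features
  standardized by training statistics, SVM trained (scikit-learn SVC,
  gamma="scale"). The leakage canary test plants a label-copy probe and
  verifies chance accuracy under permuted labels.
- Metrics: confusion counts pooled across the folds of one repetition
  (not per-fold averaging); accuracy, sensitivity (case = positive) and
  specificity are means ± sd over repetitions. Best cell = highest mean
  accuracy, ties to smaller *s* then grid order.
- Per-sample log-odds: for the best cell, sigmoid (Platt) calibration fit
  on training folds (`CalibratedClassifierCV(method="sigmoid")`),
  probabilities clamped to [1e-6, 1−1e-6], `ln(p_case/p_control)` averaged
  over the repetitions in which the sample was held out.
- Permutation null: labels shuffled once per permutation (default 20,
  seeded), the full procedure re-run, best accuracy recorded; the real
  accuracy's percentile within the null sample is the overtraining
  diagnostic.

## qPCR quantification

Replicate wells are averaged per sample per miRNA (spread > 1 cycle flags
the sample but does not drop it). `ΔCt = Ct(target) − mean Ct(miR-16)` per
sample; `ΔΔCt = mean ΔCt(case) − mean ΔCt(control)`; group fold `2^−ΔΔCt`.
Because a down-regulated target has fold < 1, results are reported as a
magnitude ≥ 1 plus a direction ("up" iff case mean ΔCt is smaller — higher
ΔCt means lower expression). With complete pairs the per-pair folds are also
computed; their geometric mean equals the group fold identically, while the
arithmetic mean differs under noise — both are emitted. The group test is a
t-test on ΔCt (the log-scale quantity), Student by default; AUC scores
samples by −ΔCt, unfolded, so orientation is visible. Quantification is pure
2^−ΔΔCt — no amplification-efficiency (Pfaffl) correction.

Note that the unpaired t-test is conservative when matched-pair baseline
variation is present (positive within-pair correlation); calibration checks
of the p-value distribution therefore switch pair variation off.

## Problem sizes used in checks

Acceptance-level checks run 50 replicate cohorts at the full study
dimensions (105 × 1100 × 7) for the FDR property, 1000 random instances for
each brute-force oracle (BH, AUC, medians), 10-repetition CV at study scale
for the classifier properties, 24 simulated pairs for qPCR recovery, and a
reduced end-to-end run (10 repetitions, 3 subset sizes, 3 permutations) for
the smoke test. These sizes were chosen so the whole battery completes in a
few minutes while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- **Glog compression of dim probes.** Below the fitted glog scale
  (`x − a ≲ b`) the transform is sub-logarithmic, so planted log-scale
  effects on dim probes appear shrunk; the per-probe effect-recovery check
  is therefore exact only for probes above that scale (and in expectation
  overall). This mirrors the real behavior of generalized-log normalization.
- **Noise-free calibration is identified only up to a common affine
  reparameterization** (see gauge discussion); recovery is asserted on the
  identifiable part.
- **Classifier figures are model-bound.** Default synthetic cohorts are
  nearly separable; no attempt is made to tune the generator so that CV
  accuracies match any particular published percentage.
- The FDR property sits intentionally close to its nominal ceiling
  (π₀·α); small-sample fluctuation of the 50-cohort mean around ≈ 0.046 is
  expected.
- Expression input is a plain feature-by-sample TSV; platform raw formats
  and series-matrix importers are out of scope (documented extension point).
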