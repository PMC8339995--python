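# Methods

## Model and assumptions

Two-sample MR treats genetic variants as instruments for an exposure: each
instrument must (i) associate with the exposure, (ii) be independent of
confounders, and (iii) affect the outcome only through the exposure. The
package works entirely on summary statistics — per-variant effect estimates
β̂Xⱼ (exposure study) and β̂Yⱼ (outcome study) with standard errors — and
assumes the two studies do not share samples, so the sampling errors of β̂X
and β̂Y are independent. Binary outcomes are handled on the log-odds scale;
odds ratios are exponentiated effects.

## Instrument processing

- **Selection**: strict `p < threshold` (default 5×10⁻⁸). Boundary values are
  excluded; the survivor order is the input order.
- **Clumping**: greedy — keep the smallest-p remaining variant, drop
  neighbours on the same chromosome within the window (default 5000 kb,
  positions 1-based) with r² above threshold (default 0.01); ties on p break
  by smaller position, then lexicographic id, so output is deterministic.
  LD is a user-supplied matrix; no genotype panel is consulted.
- **Harmonization**: outcome records are aligned to the exposure's effect
  allele, allowing swapped alleles and strand complements (effect negated,
  frequency reflected when swapped). Palindromic variants (A/T, G/C) cannot
  be resolved by letters; under the default `infer_by_eaf` policy they are
  aligned by allele frequency and dropped when either frequency is missing
  or falls in the ambiguity band [0.42, 0.58]; `drop_all` removes them
  outright. Every flip and drop is logged with a reason code.
- **Instrument strength**: mean F is approximated by the mean squared
  exposure Z statistic, with a weak-instrument flag below 10.

## Estimators

All weighted regressions use weights 1/σYⱼ².

- **IVW**: slope through the origin (closed form); fixed-effect SE
  (Σβ̂Xⱼ²/σYⱼ²)^(−1/2). The random-effects variant multiplies the SE by
  max(1, √(Q/(J−1))) — a multiplicative overdispersion model floored at 1,
  so it is never narrower than fixed effects. `auto` picks random effects at
  J ≥ 3 and fixed at J ≤ 2. Inference is normal; 95% CIs use 1.959964
  throughout the package.
- **MR-Egger**: records are first oriented so β̂Xⱼ ≥ 0 (both betas negated
  together — estimates are invariant to per-variant allele flips by
  construction); then WLS with intercept (statsmodels), SEs scaled by
  max(1, √(RSS/(J−2))), p-values from t(J−2). The intercept estimates the
  average directional pleiotropy.
- **Weighted median**: Wald ratios β̂Yⱼ/β̂Xⱼ with first-order weights
  ∝ β̂Xⱼ²/σYⱼ²; sorted ratios interpolated at cumulative midpoint weight ½
  (endpoints clamp). SE is the standard deviation of seeded parametric
  bootstrap replicates (default 1000) redrawing both betas at their SEs.
  Records with β̂Xⱼ = 0 are dropped with a warning rather than propagating
  infinities.
- **Multivariable MR**: WLS of β̂Y on the K exposure-beta columns without
  intercept (standard practice; the exposures' shared instruments identify
  direct effects), SE scale max(1, √(RSS/(J−K))), normal inference. Rank
  deficiency and J ≤ K are hard errors.
- **MR-PRESSO**: observed statistic Σⱼ wⱼ(β̂Yⱼ − β̂₋ⱼβ̂Xⱼ)² with
  leave-one-out IVW slopes β̂₋ⱼ; the null redraws β̂Xⱼ* ~ N(β̂Xⱼ, σXⱼ) and
  β̂Yⱼ* ~ N(β̂₋ⱼβ̂Xⱼ, σYⱼ) (default 1000 replicates). The global p uses the
  add-one estimator, so its floor is 1/(n_sim+1). Per-variant tails use the
  plain empirical fraction — an add-one floor would make the Bonferroni
  flag threshold α/J unreachable at moderate n_sim and J ≳ 20·(1/α)/n_sim.
  Outliers (p < α/J, α configurable, default 0.05) are removed before the
  corrected IVW. The distortion test compares the raw-minus-corrected
  contrast to the same contrast under random removal of equally many
  variants; it is reported but gates nothing. All randomness is drawn in
  variant-id-sorted order so results are invariant to row order.

## Mediation

Indirect effect = β̂X·β̂M (exposure→mediator times mediator→outcome adjusted
for the exposure, the latter from multivariable MR). Delta-method SE
√(β̂X²σM² + β̂M²σX²); the second-order term σX²σM² is available via
`include_second_order` but off by default (first-order is the convention the
printed intervals follow, and the bootstrap check in the tests shows the
difference is <2% when both factors are well separated from zero). Mediated
proportion = 100·indirect/total; its CI defaults to the delta method for a
ratio of independent normals. The `ratio_of_bounds` mode (indirect CI bounds
divided by total CI bounds) is provided only because some published tables
follow that nonstandard rule; it is labelled as a compatibility mode. In the
pipeline, the total and step-1 effects use MR-PRESSO-corrected IVW only when
outliers were actually flagged, otherwise plain IVW. Report tables round
effects to 3 decimals and proportions to 1, matching the usual presentation.

## Synthetic data: what it emulates, and what a green test establishes

The generator draws independent instruments with per-allele effects
γⱼ ~ N(0.04, 0.015²) at minor allele frequencies U(0.1, 0.5) and study sizes
n = 200,000 per side — values chosen once to mimic a well-powered consortium
GWAS in which a comfortable majority of instruments clear 5×10⁻⁸ with
heterogeneous strengths (mean F ≈ 140). Standard errors follow the
standardized-trait approximation σ = 1/√(2·maf·(1−maf)·n); exposure and
outcome noise are independent (two-sample design). Pleiotropy is a direct
SNP→outcome effect on a random subset (`prop_invalid`) — mean 0 for balanced,
nonzero for directional. The mediation layer gives the mediator its own
instruments and composes linear paths, so total = direct + indirect exactly
and the true mediated proportion is known in closed form; defaults
(θ_XM = 1.087, θ_MY = 0.16, θ_direct = 0.33, ≈34.5% mediated) mirror an
adiposity→diabetes configuration. Variants are spaced 10 Mb apart on
alternating chromosomes with non-palindromic alleles, so clumping and
harmonization are exercised only where tests construct those cases
deliberately.

Not emulated: LD structure between instruments, case/control sampling beyond
SE magnitude, winner's-curse selection, allele-frequency realism, or sample
overlap. A green recovery test therefore establishes estimator correctness
under the stated world, not robustness to those features.

## Numerical choices and edge cases

- Empirical p-values: add-one for the PRESSO global test (never zero), plain
  fraction per variant (see above).
- A single instrument reduces IVW to the Wald ratio; β̂X = 0 there is a hard
  error. Degenerate Egger designs (all β̂X equal after orientation) and empty
  datasets are hard errors with stage-attributed messages in the pipeline.
- The weighted-median bootstrap and all PRESSO simulation are seeded; fixed
  seed ⇒ bit-identical results, and reports serialize with sorted keys so
  identical runs produce byte-identical JSON.
- File round-trips read floats with `round_trip` precision so written
  summary statistics reproduce exactly.

## Known limitations

- Egger's slope requires negligible instrument-measurement error (NOME): at
  n = 200,000 the attenuation is ≈ 1−I²GX ≈ 5% of the causal effect. The
  strong-instrument recovery test therefore uses an exposure GWAS of
  n = 700,000 — the actual scale of modern anthropometric meta-analyses —
  where the attenuation is below 1%. No SIMEX correction is applied.
- The delta-method proportion CI treats the indirect and total estimates as
  independent, which is approximate since both derive from the same outcome
  study.
- Correlated instruments (generalized IVW), MR-RAPS, mode-based estimators
  and Steiger filtering are out of scope.
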