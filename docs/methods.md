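# Methods

## The model

`netmr` performs two-sample Mendelian randomization (MR) from GWAS summary
statistics.  Per SNP *j*, the inputs are the estimated per-allele effect on
the exposure, β̂ₓⱼ (SE σₓⱼ), and on the outcome, β̂ᵧⱼ (SE σᵧⱼ), expressed for
the same effect allele.  Under the instrumental-variable assumptions
(relevance, no confounding of the instrument, exclusion restriction) each
valid instrument identifies the causal effect θ through its Wald ratio
β̂ᵧⱼ/β̂ₓⱼ.  For a binary outcome all effects are on the log-odds scale and
odds ratios are derived by exponentiation; they are never estimated
directly.

### Estimators

* **IVW** — weighted mean of the Wald ratios with first-order weights
  wⱼ = (β̂ₓⱼ/σᵧⱼ)².  The fixed-effect SE is (Σw)^(−1/2); the
  multiplicative-random-effects (MRE) model multiplies it by
  max(1, √(Q/(J−1))).  MRE is the package's primary mode: it equals the
  fixed-effect model under homogeneity and is conservative under
  heterogeneity, and the fixed-effect estimate is always reported alongside.
  First-order weights ignore the exposure-side sampling error; this is the
  standard choice and is accurate when instruments are strong (F ≫ 10).
* **MR-Egger** — weighted least squares of sign-oriented outcome effects on
  |β̂ₓ| with an intercept, weights 1/σᵧ².  Each SNP is oriented so the
  exposure effect is positive (the fit must not depend on arbitrary allele
  coding).  SEs carry the multiplicative overdispersion factor
  max(1, √(RSS_w/(J−2))); inference is t with J−2 df.  The intercept
  estimates the mean directional pleiotropy; the slope is the
  pleiotropy-adjusted causal effect.
* **Weighted / simple median** — the interpolated weighted median of the
  ordered ratio estimates (cumulative weight sⱼ = Σ_{k≤j} w₍ₖ₎ − w₍ⱼ₎/2,
  linear interpolation where s crosses ½), with inverse-variance or equal
  weights.  SEs come from a seeded parametric bootstrap (per-SNP betas
  redrawn from their sampling normals; default 5000 draws).
* **IVW and median p-values** are two-sided normal; Egger p-values are
  t-based.  All 95% intervals use the fixed multiplier 1.96.

### Sensitivity suite

* **Cochran's Q** with the IVW first-order weights; chi-square upper tail at
  J−1 df.
* **Egger intercept test** for directional pleiotropy (t, J−2 df).
* **MR-PRESSO**: the observed residual sum of squares — each SNP's residual
  against the *leave-one-out* IVW slope, weighted by 1/σᵧ² — is compared
  with parametric simulations drawing β̂ᵧⱼ ~ N(β̂₍₋ⱼ₎β̂ₓⱼ, σᵧⱼ) and
  β̂ₓⱼ ~ N(β̂ₓⱼ, σₓⱼ).  The global p uses the add-one estimator
  (1 + #{RSS_sim ≥ RSS_obs})/(n_sim + 1); per-SNP outlier p-values come from
  the simulated distribution of each SNP's residual contribution,
  Bonferroni-adjusted over J, and are only searched when the global test is
  significant; the distortion test compares the outlier-removed shift of the
  IVW estimate with the shifts from removing equally many random SNPs.
  Defaults: n_sim = 1000, α = 0.05; all draws seeded, results bit-exactly
  reproducible per seed.
* **Leave-one-out** IVW in the same mode as the primary analysis.

### Multivariable MR

Direct effects of K exposures are estimated by weighted least squares of
β̂ᵧ on the J×K exposure-effect matrix with weights 1/σᵧ² and no intercept
(the standard identification choice).  Instruments are selected per
exposure, unioned, and the union is clumped once jointly using each SNP's
minimum p across exposures.  SEs use the Egger-style overdispersion scale
max(1, √(RSS_w/(J−K))).  A rank-deficient design (duplicated or collinear
exposures) is an error naming the collinear pair; an exposure whose
instrument signal is exactly zero has its coefficient pinned to 0 rather
than failing, which reduces the fit to univariable IVW for the remaining
exposure.  A heuristic conditional instrument strength is reported per
exposure (mean squared residual of its betas regressed on the others', in
units of its squared SE) and flagged below 10, but never auto-excludes.

### Two-step mediation

For a triple (exposure X, mediator M, outcome Y):

* β_total — univariable IVW X→Y;
* β_EM — univariable IVW X→M on X's instruments;
* β_MO — the mediator coefficient from MVMR of Y on (M, X), i.e. M→Y
  adjusted for X.  Adjusting step 2 for the exposure makes the linear
  decomposition exact.

Then β_indirect = β_EM·β_MO with delta-method SE
√(β_EM²σ_MO² + β_MO²σ_EM²), β_direct = β_total − β_indirect (additive by
construction), and proportion mediated = β_indirect/β_total, reported as a
signed percentage.  The proportion's CI is delta-method on the ratio
(numerator and denominator treated as independent) and reported only when
the total effect is bounded away from zero; otherwise the ratio is
unstable and the CI is reported as unbounded.  Classification: *none* when
the indirect CI includes 0; *competitive* when indirect and total effects
have opposite signs (negative proportion); *full* when the direct CI
includes 0 while the indirect excludes it; *partial* otherwise.

Mediator screening requires nominal significance (α = 0.05) of both steps
plus a direction guard — no significant reverse IVW effect of the mediator
on the exposure.  No multiplicity correction is applied by default across a
screen, mirroring common practice in hypothesis-generating scans; callers
can apply Benjamini–Hochberg to the logged p-values.

## Instrument selection

Significance threshold p < 1e-5 (strict), greedy LD clumping at r² < 0.001
within a 10,000 kb window measured from the index SNP, then F = (β̂/σ̂)² > 10
(strict).  Clumping ties on p are broken by (chrom, pos, snp_id) so results
are independent of row order.  The single-SNP Wald form of F needs no
sample size or allele frequency.  The LD matrix is a required input; no
remote lookup is performed.

## Harmonization

Matching on SNP id; allele pairs reconciled as-is, by orientation swap
(sign-flip of the outcome beta, EAF → 1−EAF), or by strand complement.
Palindromic (A/T, C/G) variants cannot be resolved from allele labels: they
are kept only when both EAFs are present, both fall outside 0.5 ± 0.08 and
on the same side of 0.5; otherwise dropped and counted.  The window is a
parameter; 0.08 is the common conservative choice.  Palindromes with
missing EAF are always dropped.  Zero p-values are clamped to the smallest
positive double and logged, not dropped.

## The synthetic-data generator

`simulate_chain` emulates the statistical structure of a
protein → immune-phenotype → disease study: per-SNP true exposure effects
bⱼ ~ N(0, σ_b²), mediator effects θ_EM·bⱼ (plus mediator-specific
instrument effects when `n_snp_med > 0`), and outcome effects
θ_direct·bⱼ + θ_MO·(mediator effect) + αⱼ on the log-odds scale.  Observed
betas add analytic sampling noise: σ = 1/√(2·maf(1−maf)·n) per
standardized quantitative trait and 1/√(2·maf(1−maf)·n·φ(1−φ)) for a
binary trait with case fraction φ.  Defaults mirror the emulated cohorts:
exposure n = 2639, mediator n = 3394, outcome n = 412,181 with φ = 1.14%
(the tabulated cohort sizes of the protein panel, immunophenotype and
biobank disease GWAS this design targets).  σ_b is set so the expected
single-SNP F equals `mean_f` (default 60 — comfortably past the F > 10
filter after selection at p < 1e-5).

Design choices worth knowing:

* Effects are generated directly on the summary-statistic scale — no
  individual-level genotypes or logistic model.  That is exactly what
  summary-statistic MR methods consume and orders of magnitude faster; it
  does not emulate fine-scale LD between effect estimates, winner's-curse
  selection in the source GWAS, sample overlap, or non-collapsibility of
  the odds ratio.  Passing tests therefore validate the estimators under
  their own sampling model, not robustness to those real-data features.
* Pleiotropy αⱼ ~ N(μ_dir, σ_pleio²) attaches to exposure-block SNPs only
  and is oriented relative to the exposure-increasing allele; a constant
  attached to an arbitrary allele coding would cancel under Egger's sign
  orientation and would not constitute directional pleiotropy.
* Outlier SNPs (for MR-PRESSO experiments) are planted at the strongest
  instruments, with the pleiotropic perturbation sized so the SNP's Wald
  ratio is `outlier_scale` × the true effect.  An outlier at a weak
  instrument is statistically invisible and would make detection-rate
  experiments meaningless.
* Mediator-specific (`n_snp_med`) and outcome-specific (`n_snp_out`) SNP
  blocks exist because the M→Y path is unidentifiable in MVMR from exposure
  instruments alone (the two effect columns are proportional), and reverse
  MR needs outcome instruments.  Both default to 0.
* LD is block-diagonal (`ld_within_r2` inside blocks of `ld_block_size`),
  with blocks confined to one chromosome — sufficient to exercise clumping,
  with no population-genetic decay model.  Observed betas are drawn
  independently across SNPs even within an LD block.
* `simulate_screen` lays each trait's instruments on a disjoint block of a
  shared SNP panel, so traits are instrumented independently and a planted
  causal triple propagates effects exactly as the chain model prescribes.

### Power regimes in the screening experiments

At the emulated cohort sizes, the exposure→mediator step is the power
bottleneck of a two-step screen: with θ_EM ≈ 0.15 and ~30 instruments the
step-1 z-statistic is ≈ 4 and the planted triple is recovered in ≈ 90% of
replicate screens.  Much larger θ_EM is not a free lunch: once
θ_EM·bⱼ crosses the mediator's own significance threshold, exposure
instruments leak into the mediator's instrument set and the direction guard
(correctly) rejects the mediator because its reverse regression on the
exposure is then confounded.  The screen experiments therefore use a weak
mediated path (θ_EM = 0.15, θ_MO = 0.5, θ_direct = 0.15; proportion
mediated 33.3%), which is also the regime the emulated study reports —
mediated proportions of a few percent.  Recovery rates are reported over
replicate screens rather than a single draw.

## Numerical conventions

* All inequalities in instrument selection are strict on the printed side.
* CI multiplier fixed at 1.96 (not the exact normal quantile), so CI and
  OR-CI columns reproduce the convention of published MR tables.
* Every stochastic routine (median bootstrap, MR-PRESSO, the generator)
  takes an explicit integer seed; the package default is 20240910.
  Identical seed + config reproduces every output byte-for-byte.
* Wald ratios are undefined at β̂ₓ = 0 and raise, naming the SNP; the
  proportion mediated is undefined at β_total = 0 and raises.
* Degenerate inputs (single SNP for IVW, J < 3 for Egger/medians, J < 4
  for MR-PRESSO, J ≤ K for MVMR) raise typed insufficient-instrument
  errors rather than returning NaNs.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to run on a
single CPU in a few minutes while keeping Monte-Carlo error well inside the
asserted tolerances: 1000 replicates for IVW recovery/coverage (binomial
95% band 93.6–96.4% at that size), 500 replicates for the null-calibration
KS checks, 40 replicates at n_sim = 1000 for MR-PRESSO detection, and 8–10
replicate screens for end-to-end mediation recovery.  Coverage and
recovery experiments use enlarged cohort sizes (n_exp = 5×10⁵,
n_out = 2×10⁶) so that first-order-weight bias is negligible relative to
the quantities under test; screening experiments use the study-scale
defaults above.

## Known limitations

* No proxy-SNP lookup, liftover, VCF parsing, or reference-panel r²
  computation; the LD matrix must be supplied (the generator fabricates
  one).
* No mode-based estimators, MR-RAPS, Steiger filtering, radial MR, or
  funnel asymmetry tests beyond the Egger intercept.
* Median-estimator SEs are parametric-bootstrap only.
* The mediation CI for the proportion uses the delta method and assumes
  independent numerator and denominator; with overlapping instrument sets
  they are correlated, and the CI is approximate.
* The conditional F reported by MVMR is a heuristic screen, not the full
  covariance-aware statistic.
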