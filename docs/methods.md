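# Methods

This note documents the statistical model behind each module, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Harmonization

Outcome records are aligned to the exposure study's effect allele by
trying, in order: direct match; swapped labelling (flip the sign of the
outcome effect and complement its allele frequency); strand complement;
complement + swap.  Alleles are upper-cased on read; indels are passed
through verbatim and never complemented (strand flips of indels are not
well defined from summary data).  Anything else is rejected as an allele
mismatch.

Palindromic SNPs (A/T, C/G) are strand-ambiguous from alleles alone.  Two
modes are offered:

* **frequency-align** (default): orient by comparing the effect-allele
  frequencies; if either frequency lies in [t, 1−t] the SNP is rejected
  as unresolvable.  The default ambiguity threshold t = 0.42 keeps
  palindromes with clearly asymmetric frequencies and is configurable.
  A palindromic SNP missing a frequency in either study is rejected.
* **drop-palindromic**: the standard sensitivity analysis; every
  palindromic SNP is removed.

Exclusion lists (SNPs associated with potential confounders) are static
two-column files shipped with a run, for reproducibility; excluded SNPs
stay in the harmonized table, flagged, and contribute to no estimator.

## Estimators

All estimators work on the harmonized arrays (γ̂ⱼ, σₓⱼ, Γ̂ⱼ, σ_yⱼ).

* **IVW.** θ̂ = Σwγ̂Γ̂ / Σwγ̂² with w = 1/σ_y²; fixed-effect SE
  1/√(Σwγ̂²).  The random-effect flavor is *multiplicative*: the SE is
  scaled by √(Q/(J−1)) floored at 1, where Q = Σw(Γ̂−θ̂γ̂)².  An additive
  between-SNP variance (τ²) is deliberately not implemented; the
  multiplicative convention matches how random-effect IVW is usually
  implemented for summary-data MR.  P-values are normal.
* **Maximum likelihood.** The joint model γ̂ⱼ ~ N(gⱼ, σₓⱼ²),
  Γ̂ⱼ ~ N(θgⱼ, σ_yⱼ²) with unknown true effects gⱼ.  Profiling the gⱼ
  out analytically leaves the one-dimensional objective
  ½Σ(Γ̂ⱼ−θγ̂ⱼ)²/(σ_yⱼ²+θ²σₓⱼ²), minimized by bounded Brent iteration
  bracketed around the IVW estimate (bracket widened ×10 up to five
  times on failure).  The SE uses the observed information — the
  numerical curvature of the profile log-likelihood at the optimum
  (central differences, step 1e−5·(1+|θ̂|)); a likelihood-ratio profile
  interval would be the alternative, and the choice matters little at
  the instrument strengths this package targets.
* **Weighted median.** Wald ratios θⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE
  σ_yⱼ/|γ̂ⱼ| (the second-order term (Γ̂²σₓ²)/γ̂⁴ is available by option
  but negligible at F ≈ 100).  Ratios are sorted; weights 1/SE²
  normalized; the estimate linearly interpolates the ordered ratios at
  cumulative-midpoint weight 0.5.  The SE is a parametric bootstrap
  (default 1,000 resamples of γ̂, Γ̂ from their sampling distributions,
  seeded; fewer than 100 triggers a warning).
* **MR–Egger.** All SNPs are oriented so γ̂ⱼ ≥ 0, then Γ̂ is regressed on
  γ̂ *with* intercept, weights 1/σ_y².  The intercept estimates average
  directional pleiotropy; its two-sided p is the pleiotropy test.  Both
  coefficients use the multiplicative scaling √(Q/(J−2)) floored at 1
  and Student-t inference with J−2 df — slope and intercept inference at
  small J is the one place where normal quantiles are clearly too
  narrow.
* **MVMR.** Γ̂ regressed without intercept on the primary exposure's γ̂
  plus one column per covariate exposure (per-SNP effects from that
  covariate's GWAS), weights 1/σ_y², multiplicative scaling with df =
  J−K.  SNPs missing any covariate effect are dropped and counted.  A
  rank-deficient design raises an error naming the exposures; a
  covariate column that is identically zero is dropped from the
  regression (coefficient reported as 0) so the fit degrades to fewer
  exposures instead of failing.
* **Diagnostics.** Cochran's Q with df = J−1 (J−2 after Egger); per-SNP
  F = (γ̂/σₓ)² with the overall F defined as their mean (the common
  single-number convention when no formula is stated); leave-one-out IVW
  with a flag for omissions whose estimate leaves the all-SNP 95% CI.
* **Significance annotation.** p < 0.05 is starred suggestive, p < 0.01
  (0.05/4, four diseases) double-starred significant.  Thresholds
  annotate rows; they never filter them.

## Causal-effect clustering

Per-variant ratios are modeled as a mixture with, for each candidate
K = 0..K_max: K substantive components N(μₖ, seⱼ²), a null component
N(0, seⱼ²), and a junk component uniform over the observed ratio range
inflated by 20%.  Each variant keeps its own measurement variance
(optionally inflated by a constant), so component variances cannot
collapse and EM is stable; only the μₖ and mixing proportions are free.
EM runs to tolerance 1e−8 (max 10,000 iterations) from n_starts = 5
seeded k-means++ initializations; the log-likelihood is checked to be
non-decreasing at every step.  K is selected by BIC with 2K+1 free
parameters, ties broken toward smaller K; the full per-K BIC trace is
kept so users can audit why clusters appear or disappear across
instrument-curation choices.  A variant is hard-assigned only where its
posterior exceeds 0.8, and a cluster is *displayed* only with ≥ 4
assigned variants (both configurable); cluster means are reported in
ascending order so relabeling cannot change results.

## LD-score regression

For panels of paired association z-scores: E[z²] = intercept + n·h²·ℓ/M
per trait, and E[z₁z₂] = intercept + √(n₁n₂)·ρ_g·ℓ/M across traits, with
ℓ the SNP's LD score and M the denominator SNP count.  Slopes are
estimated by weighted regression with heteroskedasticity weights
1/(1+n·h²·ℓ/M)² — one re-weighting pass from an initial unweighted fit,
and the geometric mean of the two traits' weights for the cross
regression.  This is a simple, documented approximation to the reference
implementation's two-step weighting (which additionally corrects for
double-counting in LD); it is unbiased for the slope and accurate enough
that planted parameters are recovered well within the jackknife SEs.
Genetic correlation is r_g = ρ̂_g/√(ĥ₁²ĥ₂²).  SEs come from a
delete-a-block jackknife over 200 contiguous blocks (configurable), with
the *full ratio* recomputed per deleted block and regression weights
frozen at their full-sample values.  Free intercepts absorb confounding
(univariate) and sample overlap (bivariate).  If either heritability
estimate is non-positive, r_g is undefined and a flagged result is
returned rather than an exception; |r_g| > 1 is reported and flagged,
since a ratio of estimates may legitimately exceed 1.

## Meta-analysis and power

Published odds-ratio rows are converted to log-scale inputs with
se = (ln high − ln low)/(2·1.959964).  The cross-disease pool is a
fixed-effect inverse-variance average; recomputing from printed
two-decimal rows reproduces the pooled estimates to two decimals, which
is why the fixed-effect model was adopted.  Cochran's Q across studies
is reported but no random-effects pooling is attempted at 3–4 studies.

Power for a binary outcome uses the normal approximation
power = Φ(−z₁₋α/₂ + |ln OR|·√(N·r²·φ(1−φ))) with N the total sample,
φ the case fraction and r² the exposure variance explained by the
instruments — the standard analytic calculator for summary-data MR with
case-control outcomes.

## Synthetic data generator

`gen_two_sample` emulates the statistical structure the estimators
assume, directly on the summary scale:

* Defaults mirror the motivating study design: J = 99 instruments,
  exposure n = 941,280, outcome 14,361 cases / 43,923 controls
  (rheumatoid-arthritis scale), instruments jointly explaining 1% of
  exposure variance.  These imply per-SNP F ≈ 1 + n·h²/J ≈ 96 — the
  order of magnitude of a strong modern instrument set.
* Effect-allele frequencies are uniform on (0.05, 0.95); SEs follow
  σₓ = 1/√(2pq·n) (standardized continuous trait) and
  σ_y = 1/√(2pq·N·φ(1−φ)) (log-OR scale).
* True exposure effects are oriented positive — the convention of
  published instrument lists, which report the exposure-increasing
  allele.  This matters: directional pleiotropy only biases IVW when
  the instruments share an orientation.
* Pleiotropy scenarios: *balanced* (α ~ N(0, sd²) everywhere),
  *directional* (α ~ N(mean, sd²) on a fraction of SNPs, spread evenly
  over the instrument-strength ranks so the invalid **weight share**
  equals the stated fraction — robustness guarantees like the median's
  50% breakdown point are about weight, not counts), and *confounder*
  (a fraction of SNPs get loadings on a latent confounder that feeds
  both exposure and outcome, violating exclusion as a group; the
  matching confounder-GWAS records, n = 700,000, are emitted for MVMR).
  Confounder defaults (loadings explaining 2% of confounder variance,
  exposure and outcome loadings 0.5) keep the measurement error of the
  confounder GWAS small relative to the loadings, which the MVMR
  repair implicitly assumes.
* `gen_clustered` plants groups of variants with common ratio values,
  plus null and broadly scattered junk variants; `se_scale` multiplies
  the outcome SE (0.1 gives the tight, well-separated clusters used in
  recovery checks).
* `gen_ldsc_panel` draws LD scores from a gamma distribution (shape 2,
  scale 50: right-skewed, mean 100, like empirical LD scores) and
  (z₁, z₂) per SNP from the exact bivariate normal implied by the
  regression model, with an optional sample-overlap covariance.

What the generator does **not** emulate: LD between instruments
(instruments are modeled independent, as after conditional-and-joint
selection), individual-level genotypes, linkage-induced correlation of
z-scores between neighboring panel SNPs, allele-frequency differences
between studies, population stratification, and non-linear (U-shaped)
exposure-outcome relationships.  Passing tests therefore demonstrate
correctness of the estimators under their stated assumptions, not
robustness to every failure mode of real data.

## Problem sizes used in tests and the acceptance script

Simulation studies are sized to be decisive yet quick: 2,000 replicates
for type-I-error calibration (Monte-Carlo SE ≈ 0.005 at the 0.05 level),
500 for bias comparisons (weighted-median robustness, MVMR confounder
adjustment), 100 seeds for cluster recovery and for LD-score r_g
coverage (panels of M = 50,000 SNPs), and 10,000 replicates for SE
calibration of the generator itself.  The ~1% weak-instrument
attenuation implied by F ≈ 96 is visible in recovery studies and is
accounted for where relevant.

## Known limitations

* No proxy-SNP lookup: instruments absent from an outcome study are
  dropped (the match rate is logged and recorded in the manifest).
* No MR-PRESSO/contamination-mixture/mode-based estimators, no Steiger
  filtering, no SIMEX-adjusted Egger.
* LDSC module assumes pre-aligned panels (no munging) and does not do
  partitioned heritability or constrained-intercept fits.
* The clustering model fixes component variances at the per-variant
  measurement variance; genuinely over-dispersed clusters would need
  the variance-inflation option.
* Harmonization cannot rescue palindromic SNPs with near-0.5
  frequencies; they are rejected by design.
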