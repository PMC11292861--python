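# Methods

`medmr` implements a complete two-sample, two-step mediation Mendelian
randomization (MR) workflow over GWAS summary statistics, together with a
synthetic-data generator that makes every stage testable without any
external download. This note records the statistical model, the defaults
and why they were chosen, the numerical conventions, and what the test
suite does and does not demonstrate.

## The causal model

Two-sample MR treats genetic variants as instruments: a variant's effect on
an exposure (`beta_exp`, with standard error `se_exp`) and on an outcome
(`beta_out`, `se_out`) are estimated in *different* GWAS samples, and under
the instrumental-variable assumptions the per-variant Wald ratio
`beta_out / beta_exp` estimates the causal effect of the exposure on the
outcome.

The two-step mediation design decomposes a total exposure→outcome effect
β1 into an exposure→mediator path β2 and a mediator→outcome path β3, each
estimated by univariable MR with its own instrument set:

- proportion mediated = β2·β3 / β1,
- S = sqrt(β2²·se2² + β3²·se3²),
- 95% CI = ((β2·β3 − S)/β1, (β2·β3 + S)/β1), endpoints re-ordered after
  the division when β1 < 0.

Two deliberate conventions here:

1. **The S pairing.** The formula above pairs each coefficient with its
   *own* standard error. The standard first-order delta method for the
   variance of a product pairs each coefficient with the *other* one's
   standard error (`S_delta = sqrt(β2²·se3² + β3²·se2²)`). The two coincide exactly when se2 = se3 (property-tested).
   The own-SE pairing is the default for fidelity with the convention of
   the headline results this package reproduces; the delta variant is
   selectable (`formula="delta"`) and reports include both intervals.
2. **β1 enters as a constant.** No uncertainty in β1 is propagated into
   the CI; the interval formula divides by β1 as a plain number. se1 is
   carried in the result object for transparency but used nowhere.

A chain is *consistent* only when sign(β2·β3) = sign(β1); a zero indirect
effect is inconsistent by convention. Inconsistent chains are computed and
carried but flagged invalid-for-reporting — multivariable MR is out of
scope, so there is no direct-effect adjustment that could rescue them.

## Instrument selection

- p-value screen: strict `p < 1e-5` by default (the conventional relaxed
  threshold for exposures with few genome-wide-significant hits; the
  reverse direction uses `5e-6`).
- LD clumping: greedy, lowest-p-first. An index variant claims and
  discards every unclaimed same-chromosome variant within ±`window_kb`
  (default 10,000 kb, i.e. a 10 Mb radius) whose r² with it exceeds
  `r2_threshold` (default 0.001). Ties on p break by smaller position,
  then lexicographic id, making output independent of input row order.
  r² comes from a user-supplied or simulated `LDMatrix`; no reference
  panel is consulted.
- Weak-instrument filter: per-variant `F = beta²/se² >= 10`. Note that
  after a `p < 1e-5` screen this filter is vacuous (that p-value already
  implies F > 19.5); it only bites for looser thresholds, and it is kept
  because both knobs are exposed independently.

## Harmonization

Outcome effects are re-expressed per copy of the exposure's effect allele:
swapped alleles negate `beta_out` and complement `eaf_out`; strand
complements are resolved through the base-complement map. Palindromic
variants (A/T, C/G) cannot be strand-resolved from letters alone, so by
default (`drop_ambiguous`, EAF window 0.08) those with allele frequency in
[0.42, 0.58] on either side — or missing — are dropped, and the remainder
are oriented by EAF agreement; `drop_all` is available for strictness.
Variants absent from one table are excluded and counted; no proxy lookup
is attempted.

## Estimators

All five standard summary-data estimators are implemented:

- **IVW**: weighted regression of `beta_out` on `beta_exp` through the
  origin, weights `1/se_out²`. Default standard errors are multiplicative
  random effects, `se_fixed · max(1, sqrt(Q/(n−1)))` — the floor at 1
  means the model never reports *less* uncertainty than fixed effects.
- **MR-Egger**: the same weighted regression with an intercept, after
  orienting every pair to `beta_exp >= 0`; slope = causal estimate,
  intercept = mean directional pleiotropy. Inference uses t with n−2 df.
- **Weighted median**: Wald ratios ordered, weights ∝ inverse ratio
  variance; the estimate interpolates at cumulative weight 0.5. SE by
  seeded parametric bootstrap (default 1000 draws; the seed is a required
  argument in the API and defaults to 1 only in the CLI).
- **Simple / weighted mode**: normal-kernel density over the ratios with
  bandwidth `bandwidth_factor · 0.9 · (1.4826·MAD) · n^(−1/5)`; the
  estimate is the density argmax on a 2048-point grid spanning the ratios
  ±3 bandwidths; SE by seeded parametric bootstrap.

Ratio variances for the median, modes and Cochran's Q use the first-order
approximation `se_out²/beta_exp²`; `second_order=True` adds the
`beta_out²·se_exp²/beta_exp⁴` term. P-values are two-sided normal except
for Egger's t. All p-values are clamped into (0, 1] so degenerate
zero-residual fits cannot emit 0 or NaN.

Diagnostics: Cochran's Q on the ratio scale against the fixed-effects IVW
estimate (df = n−1, chi-square upper tail), the Egger intercept test, and
leave-one-out IVW, flagging a variant whose removal flips the estimate's
sign or its nominal (p < 0.05) significance.

## The decision procedure

`choose_primary_method` selects MR-Egger as the primary estimate when the
Egger intercept test fires (p < 0.05, strict), IVW otherwise — pleiotropy
detected means the pleiotropy-robust slope is reported. The metabolite
screen applies Benjamini–Hochberg FDR over the whole battery of primary
p-values and declares discoveries by the joint rule `p < 0.05 AND q < 0.2`
(both strict). The exposure screen is deliberately *not* FDR-corrected —
only the large metabolite family is — and this asymmetry is intentional.
Reverse MR instruments the *outcome* at the relaxed `5e-6` threshold and
excludes any mediator it hits at IVW p < 0.05; untestable mediators are
retained with a warning, never silently dropped. Exposures with fewer than
three usable instruments are reported as underpowered: IVW still runs with
two instruments, a single instrument falls back to the Wald ratio.

BH q-values are delegated to `statsmodels.stats.multitest.multipletests`;
the test suite checks them against a literal step-up enumeration. The
Egger fit is a `statsmodels` WLS. Everything else is authored here.

## The synthetic-data generator

The generator emits summary statistics directly — true effect plus
sampling noise — rather than simulating genotypes; two-sample MR consumes
nothing else, and this keeps replicate studies fast and the truth exact.
Structure:

- Exposure instruments carry effects γ_j = U(0.5, 1.5) ·
  `instrument_effect_sd` (default 0.08), coded on the exposure-increasing
  allele so that "directional" pleiotropy keeps a well-defined sign under
  Egger's orientation. A `weak_fraction` is rescaled to F ≈ 10.
- The mediator has its own instruments (default sd 0.15, typical of
  strongly heritable metabolite signals) — without them β3 could not be
  estimated — and the outcome can be given its own instruments for
  reverse-MR tests.
- The outcome effect of an exposure instrument is
  `(direct + β2·β3)·γ_j + α_j` with α_j optional pleiotropy (balanced or
  directional, on a chosen fraction of instruments). Setting
  `reverse_effect` nonzero switches the mediator downstream of the
  outcome, the scenario the reverse-MR gate must catch.
- SEs follow `1/sqrt(n)` under a standardized-genotype convention.
  Defaults use the motivating study's sample sizes: 18,340 (microbial
  exposure), 8,299 (metabolite), and for the binary outcome the
  case-control *effective* size 4·ncase·nctrl/n ≈ 18,800 rather than the
  raw 377,988, because the `1/sqrt(n)` model lives on the effective-n
  scale for log-odds.
- Default effect sizes reproduce the headline chain: β2 = 0.16,
  β3 = −0.21, direct = −0.2664, so total = −0.30 and the implied true
  proportion mediated is 0.112.
- LD blocks replicate a tag instrument's true effect attenuated by
  r = sqrt(r²), with tag-correlated sampling noise, and record r² in the
  emitted matrix. Null variants have zero effect everywhere.

What the generator does **not** emulate: realistic allele-frequency
spectra, LD beyond simple equicorrelated blocks, sample overlap between
the GWAS, population stratification, or binary-trait likelihood effects
beyond the effective-n Gaussian approximation. Tests passing on this
generator therefore certify the *estimators and decision logic*, not
robustness to those real-data complications.

## Monte-Carlo test designs and problem sizes

The calibration suite uses a deliberately strong-instrument design
(exposure n = 500,000, effect sd 0.15, mean F ~ 10³). This isolates
estimator calibration from weak-instrument attenuation, a real but
separate phenomenon of order 1/F that would otherwise dominate the bias
checks. Replicate counts: 500 for IVW bias/coverage and Egger-intercept
recovery, 2000 for the Q type-I error, 500 for the weighted median, 200
for end-to-end proportion recovery, 300 per arm for the reverse-MR gate —
sizes at which each check resolves the quantity it measures while the
whole suite runs in a few minutes on one CPU.

Two robustness checks for invalid instruments are designed differently on
purpose. With *directional* pleiotropy concentrated on fewer than half the
instruments, the weighted median is biased by an amount proportional to
the per-ratio sampling noise (it converges to a shifted quantile of the
valid-ratio distribution as n grows; only increasing instrument precision
removes the shift), so an unbiasedness check under directional
contamination would fail for any estimator of this family. Accordingly:
the unbiasedness check plants 40% invalid instruments with *balanced*
(mean-zero) pleiotropy, where the median is genuinely centered; a separate
check plants a large directional offset on 40% of instruments and asserts
the honest, attainable property — the weighted median's bias stays below
half of naive IVW's. The Egger intercept check plants directional
pleiotropy on *all* instruments (mean 0.005), which is what the intercept
estimates under the InSIDE assumption.

## Numerical conventions and degenerate inputs

- All threshold comparisons are strict (`<`), including p-value screens,
  the joint FDR rule, the Egger-intercept switch and the F filter.
- Estimators are invariant to variant order; seeded bootstraps are
  bit-reproducible.
- `beta_exp = 0` raises a degenerate-instrument error (the Wald ratio is
  undefined); an all-equal `beta_exp` design raises a rank-deficiency
  error from Egger; too few instruments raise an explicit
  insufficient-instruments error rather than returning NaN.
- Missing `eaf`/`n` are the only permitted missing fields and serialize as
  `NA`; positions are 1-based; alleles are single uppercase bases.
- Reports are written with `%.10g` float formatting and sorted JSON keys,
  so identical runs are byte-identical.

## Known limitations

- No multivariable MR, cML-MA, MR-PRESSO, Steiger filtering, LD-score
  regression or proxy-variant lookup; these are outside the package's
  scope.
- The LD model is a block-equicorrelation idealization.
- The bootstrap SEs for median/mode estimators are parametric (normal
  resampling of ratios), not resampling of variants.
- The mediation CI treats β1 as fixed (see above); users wanting full
  uncertainty propagation should bootstrap the whole pipeline.
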