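# Methods

## Scope and model

`mrscreen` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics: genetic variants robustly associated with an exposure
serve as instrumental variables, and the causal effect of the exposure on an
outcome is estimated from the ratio of outcome to exposure per-allele
effects across instruments.  The package covers the full screening workflow
used in gut-microbiome → immune-mediator → kidney-outcome studies:
instrument selection, harmonization, six estimators, sensitivity
diagnostics, multiple-testing screening, bidirectional (reverse) MR, and
two-step mediation with signed mediation proportions.

The identifying assumptions are the usual ones: instruments are associated
with the exposure (relevance), independent of confounders, and affect the
outcome only through the exposure (no horizontal pleiotropy).  The
estimator battery spans different relaxations of the third assumption:
IVW assumes all instruments valid; MR-Egger allows directional pleiotropy
under InSIDE (instrument strength independent of direct effects); the
weighted median requires only a valid majority of weight; the mode
estimators require only a valid plurality.

## Instrument selection

Selection applies, in order: a per-trait-class significance threshold
(defaults 1e-5 for microbiome taxa/pathways and immune cells, 5e-6 for
cytokines, 5e-8 for outcomes acting as exposures in reverse MR); greedy LD
clumping (keep the most significant variant, drop others within 10,000 kb
with r² ≥ 0.001, ties broken by chromosome/position/rsid for determinism);
and a weak-instrument filter.  Two instrument-strength statistics are
computed: the per-variant F = (β/SE)², which drives the F ≥ 10 exclusion,
and the aggregate F = (R²/K)·(N−K−1)/(1−R²) with R² = 2·EAF·(1−EAF)·β²,
reported for instrument sets with known sample size.  LD is pluggable
(dense matrix, long table, or distance-only); missing pairs default to
r² = 0 with a warning, and a strict mode raises instead.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: exact matches
are kept; swapped alleles flip the outcome beta (and EAF); strand flips are
attempted through base complement before declaring incompatibility;
palindromic variants (A/T, C/G) are always removed — EAF-based rescue is
deliberately not attempted because allele frequencies near 0.5 make it
unreliable.  Every input variant receives an action label
(kept/flipped/dropped_*) and the labels partition the input, so no variant
disappears silently.  Duplicate rsids keep the smallest p-value.  For
multivariable MR, all traits are aligned onto the outcome's effect alleles
by the same pairwise machinery.

## Estimators and reporting conventions

All standard errors reported for IVW, Egger and MVMR carry a multiplicative
over-dispersion factor √(max(1, RSS/df)) — the random-effects convention
that widens intervals under heterogeneity but never narrows them.  Both the
fixed-effects and random-effects IVW are always reported; the
random-effects form is the primary estimate.  95% intervals are
estimate ± 1.96·SE and p-values are two-sided normal throughout.  For
binary outcomes, odds ratios exp(β) with exponentiated intervals are
reported alongside the log-odds scale.

The weighted median uses the cumulative-weight-percentile convention with
linear interpolation; its SE is the standard deviation of parametric
bootstrap replicates (effects redrawn from normal(observed, SE); exposure
effects redrawn when exposure SEs are available, held fixed otherwise).
The mode estimators use a normal-kernel weighted density with the modified
Silverman bandwidth 0.9·min(sd, 1.4826·MAD)·k^(−1/5)·φ (φ = 1 by default),
evaluated on an odd-length grid with quadratic peak refinement so symmetric
samples return their exact centre; their SE is the normalized MAD of
bootstrap replicates, which is robust to the occasional bootstrap draw
whose mode jumps between ratio clusters.  Bootstrap seeds are mandatory;
there is no hidden global RNG state anywhere in the package.

MR-Egger orients every variant so the exposure effect is positive (the
intercept is otherwise sign-ambiguous) and drops zero-effect variants with
a warning.  The Wald ratio uses the first-order delta SE (|SE_out/β_exp|),
with a second-order option.

## Sensitivity diagnostics

Cochran's Q is computed about the fixed-effects IVW slope (which minimizes
the weighted RSS, so Q is well defined) with a χ²(k−1) reference.  Note Q
is exactly calibrated only at a zero causal effect; with a nonzero effect,
exposure-side measurement error contributes an extra θ²·SE_x² per variant,
a known small inflation.

MR-PRESSO follows the parametric-simulation recipe: the observed statistic
is the weighted RSS about each variant's leave-one-out IVW slope; its null
distribution comes from redrawing outcome effects around the leave-one-out
predictions (and exposure effects around their observed values).  Empirical
p-values use (r+1)/(n_sim+1) so they are never zero; the per-variant
outlier test is Bonferroni-adjusted across instruments; the corrected
estimate is IVW after removing flagged outliers; and the distortion test
compares the observed correction against removal of random variant subsets
of the same size.  The default simulation count is 1000 (a package default;
the significance threshold for outlier removal defaults to 0.05), and runs
are bit-reproducible given a seed.

The Egger intercept block inside a sensitivity report is taken verbatim
from the fitted Egger estimate (single source of truth).

## Screening and classification

A screening batch processes one declared family (one exposure class against
one outcome).  Classification is a pure function of four inputs: IVW
p < 0.05, IVW/Egger sign agreement (zero counts as disagreement),
Benjamini–Hochberg q < 0.05 → significant; IVW p < 0.05 without the
corrected pass → suggestive; otherwise null; exposures with no usable
instruments → failed, with the row retained.  The Bonferroni threshold
α/m over the family is reported alongside (0.05/41 ≈ 0.0012 for a 41-trait
cytokine panel).  Heterogeneity or pleiotropy rejections (Q, Egger
intercept, or MR-PRESSO global p ≤ 0.05) demote a nominally significant
record to a separate `failed_sensitivity` status rather than rewriting its
classification: the diagnostics reject ~5% of perfectly clean records each
by construction, and keeping the gate in its own column preserves both the
audit trail and the purity (and idempotence) of the classification.

Reverse MR swaps the roles — the outcome becomes the exposure at the
genome-wide 5e-8 threshold — and labels results `direction=reverse`.

## Two-step mediation

Step 1 estimates β₁ (exposure → mediator) by IVW on the exposure's
instruments; the total effect β_total (exposure → outcome) uses the same
instruments.  Step 2 estimates β₂ (mediator → outcome) by multivariable
IVW over the union of exposure and mediator instruments with the exposure
adjusted for, so β₂ is a direct effect; a UVMR fallback is available.  The
mediated effect is the product β₁·β₂ with the first-order delta-method SE
√(β₁²SE₂² + β₂²SE₁²) and a normal interval (a bootstrap interval was
considered; the delta method was chosen as the default because the product
of two well-estimated effects is near-normal at these precisions).  The
mediation proportion is the signed percentage 100·β₁β₂/β_total; sign
disagreement with the total effect (inconsistent mediation/suppression) is
flagged, not hidden.  MVMR reports approximate conditional F statistics
(weighted residual variation of each exposure about the others over its
measurement variance) as an instrument-strength diagnostic.

A packaged fixture carries the 22 published pathway rows
(β₁, β₂, β_total, printed mediated effects, intervals and proportions) for
regression tests of the product-method arithmetic.  Replaying the printed
betas reproduces 18/22 printed mediated effects exactly at printed
precision and the remaining rows within one unit in the last printed
digit; recomputed proportions agree within 0.03 percentage points.  These
residual discrepancies are artifacts of the source table rounding its own
inputs, not of the arithmetic.  One row prints five decimals where the
rest of the table uses four; it is compared at the table-wide four-decimal
precision.

## Synthetic data: what it emulates and what it does not

Summary statistics are generated directly at the summary level: each
variant's observed effect is its true effect plus normal noise with
SE = 1/√(2·EAF·(1−EAF)·n), the per-allele coefficient SE for a
standardized trait at sample size n.  The causal diagram is
exposure →(β₁)→ mediator →(β₂)→ outcome with a direct path θ_direct, so
θ_total = θ_direct + β₁β₂ holds by construction.  Four variant roles
exist: exposure instruments (effect γ), mediator-specific instruments
(δ; these make the mediator identifiable in MVMR), outcome-specific
disease loci (κ; these give reverse MR realistic instruments that carry no
exposure signal), and null variants.  Horizontal pleiotropy adds a direct
outcome effect α to a configurable fraction of the exposure's instruments:
balanced (zero mean), directional (mean μ_α aligned with the
exposure-raising allele — alignment matters, because Egger's bx > 0
orientation would otherwise cancel a sign-independent mean to balanced),
or correlated (α = ρ·γ + noise, violating InSIDE).

Instrument-strength presets, chosen once: `strong` (γ ∈ 0.06–0.14, mean
F ≈ 30–60 at the default exposure n = 10⁴ — the regime typical of
microbiome GWAS hits), `weak` (mean F ≈ 8, to exercise the weak-instrument
filter), `spread` (γ ∈ 0.02–0.20, the wide strength spread that Egger
regression needs for a precise intercept), and `very_strong` (γ ∈ 0.3–0.5
with exposure n = 10⁵, mean F in the thousands).  Default sample sizes
(exposure 10⁴, mediator 5×10⁴, outcome 2×10⁵) mimic the scale asymmetry of
microbiome panels versus disease consortia without reproducing any
specific cohort.

The generator does not simulate individual-level genotypes, real LD maps,
allele-frequency-dependent architectures, sample overlap between cohorts,
winner's-curse selection, or population stratification.  Consequently,
passing tests demonstrate the correctness and calibration of the
estimators under their stated assumptions — not robustness to those
additional real-data complications.

## Validation-study conditions and numerical choices

The statistical acceptance checks fix these study conditions:

- **Type-I error**: global null, 50 strong instruments, 2000 replicates.
  The fixed-effects IVW p-value is the measured test: under homogeneity it
  is the exactly calibrated one, whereas the random-effects multiplicative
  SE (scale √max(1, Q/(k−1))) can only inflate and is therefore
  deliberately conservative (~0.045 measured).
- **Parameter recovery** (β₁ = 0.4, β₂ = 0.3, θ_direct = 0.1; 500
  replicates): run with the `very_strong` preset because IVW carries a
  regression-dilution bias of order 1/F̄; at mean F ≈ 40 that bias (~2.5%
  relative) would dwarf the Monte-Carlo resolution of the mean, while at
  mean F ≈ 10³ it is an order of magnitude below it.  This is a statement
  about what the check can resolve, not a claim that microbiome
  instruments are this strong.
- **Median robustness**: 10 instruments with 40% carrying a +0.5
  ratio-scale shift (correlated pleiotropy, ρ = 0.5).  Any one-sided
  contamination moves the weighted median's population quantile by
  ≈ 0.97σ_ratio, so the honest criterion is bias small relative to the
  per-replicate Monte-Carlo dispersion (measured ≈ 0.46 sd) while IVW is
  biased by many dispersion units (measured ≈ 6 sd).  Ten instruments is
  typical of a microbiome exposure after clumping.
- **Egger power**: directional pleiotropy μ_α = 0.015 (≈ 4 outcome-SEs),
  σ_α = 0.004, 50 `spread` instruments, exposure n = 10⁵ — sized at design
  time so a correctly implemented intercept test has comfortable power;
  the check validates the implementation, not a universal power claim.
- **MR-PRESSO**: a 10σ outlier planted among 30 instruments, n_sim = 1000,
  200 replicates for detection; 200 clean replicates for the global test.
- **Screening**: 200 panels of 20 exposures (one causal, θ = 0.3, 30
  strong instruments) screened with IVW+Egger and diagnostics limited to
  Q and the Egger intercept, keeping the 200-replicate study inside a
  practical runtime; single-run examples use the full battery.

Other numerical choices: clumping ties break lexicographically; empirical
p-values use (r+1)/(n+1); p-values that underflow to zero at extreme
z-scores are accepted by the FDR step; summary files never print p = 0
(clamped at the smallest positive double); an identically-zero MVMR
exposure column is reported as unidentified (effect 0, SE ∞) rather than
collinear; all replicate studies derive per-task seeds from one root seed
via seed sequences.

## Known limitations

- Weighted-median and mode SEs are bootstrap-based and thus seed-dependent
  at the ~1% level for the default replicate counts.
- Conditional F statistics in MVMR use a weighted-residual approximation,
  not the full Sanderson–Windmeijer covariance treatment.
- The MR-PRESSO distortion test uses random outlier-index assignment as its
  reference distribution; with very few instruments its resolution is
  limited by the number of distinct subsets.
- No Steiger directionality filtering, contamination-mixture, MR-RAPS or
  Rucker model selection; no proxy-variant lookup or liftover.
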