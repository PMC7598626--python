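# Methods

## The two-stage corrected outcome

The quantity of clinical interest — the implant volume that would have
produced symmetric breasts — is never observed directly. It is constructed
from the inserted implant and the residual asymmetry seen in three-month
postoperative 3D surface imaging:

    I_ideal = I_inserted − β · (V_recon_post − V_healthy_post)

β is the cohort-level OLS slope of inserted implant volume on preoperative
healthy breast volume. The rationale: breast volume and implant volume are
not on the same scale (a 100 cc breast-volume difference does not correspond
to a 100 cc implant difference), and β is exactly the empirical exchange
rate between the two. The naive variant (β = 1, plain addition/subtraction
of the postoperative difference) is retained for comparison and is strictly
worse at recovering a known ground truth whenever the true β ≠ 1.

Two deliberate choices in the correction stage:

- **β is estimated in-sample** on the same cohort being corrected, matching
  the clinical procedure. The corrected outcome therefore carries the
  sampling error of β̂; the paired bootstrap propagates it (below).
- **β̂ is used at full precision.** Rounding to two decimals (as a published
  slope would be quoted) is available via `round_beta` for sensitivity
  analyses.
- **Negative corrected volumes are retained**, not clipped, and flagged with
  a warning. Clipping would bias the downstream regressions; negative values
  essentially only arise under the naive (β = 1) variant, which over-corrects.

## Prediction models and their comparison

The four reported models are simple OLS fits with intercept
(inserted/ideal × weight/volume). For a simple regression R² is the squared
Pearson correlation; this identity is enforced to 1e-10 in the tests.

Comparing R² between the two predictors of the *same* outcome on the *same*
patients is a dependent comparison. Two methods are provided:

- **Paired patient-level bootstrap** (default, 5000 replicates): resample
  patients with replacement, re-estimate β̂ on the replicate, rebuild the
  corrected outcome, refit both models, and form the two-sided percentile
  p-value of ΔR² against 0. Resampling patients (rather than residuals)
  keeps the dependence between the two predictors intact, and re-estimating
  β̂ per replicate propagates the stage-1 uncertainty into the comparison.
  A fixed-outcome variant (`propagate_beta=False`) is exposed for
  sensitivity.
- **Steiger's z** for dependent overlapping correlations, as a fast
  closed-form alternative. It treats the corrected outcome as fixed data.

Both are calibrated: under a symmetric null with two equally informative
predictors at n = 56, the observed type-I error over 500 simulated cohorts
is 0.068 (bootstrap) and 0.048 (Steiger) at nominal α = 0.05 — the
percentile bootstrap is mildly anticonservative at this sample size, which
is typical.

The residual-analysis battery is fixed to Shapiro–Wilk (normality),
Breusch–Pagan against the predictor (homoscedasticity), and a t-test on a
centred quadratic term (RESET-style linearity), each at α = 0.05, with no
multiplicity correction (mirroring a single-comparison design). A
zero-residual fit is reported as non-applicable rather than passed.

## The synthetic cohort generator

### What it emulates

The generator reproduces, as *population* quantities, the published summary
structure of a 56-patient unilateral DTI series: the marginal moments of
healthy-breast volume V (322.9 ± 150.0 cc) and mastectomy specimen weight W
(287.6 ± 128.2 g); the preoperative asymmetry distribution; the regression
relations of inserted (slope 0.66, intercept 71 cc, R² 0.88) and ideal
implant volume (slope 0.78, intercept 25 cc, R² 0.90) on V; and the weight
relations (corr(I_inserted, W) = 0.900, ideal-on-weight R² = 0.759).

### Generative mechanism

Per patient, hierarchically (all noise normal, independent unless stated):

1. `V ~ TruncNormal(μ̃, σ̃; 50–1500 cc)`, with the *parent* parameters μ̃, σ̃
   solved numerically so the truncated mean and SD equal the targets exactly
   (moment calibration). A log-normal marginal is available as a config
   switch for skew studies.
2. `W | V` is linear in V with residual SD chosen so mean, SD and
   corr(V, W) are exact given V's calibrated moments.
3. Signed asymmetry `d ~ N(0, 19.80)` %, `V_affected = V(1 − d/100)`.
4. `I_inserted = 0.66·V + 71 + ε_in`, with ε_in orthogonal to V and carrying
   a small residual correlation with W (through W's residual) so that
   corr(I_inserted, W) hits 0.900.
5. True ideal `I* = 0.78·V + 25 + ε_id`, ε_id independent of V and W.
6. `V_healthy_post = V(1 + m)` with 3% remeasurement noise m, and
   `V_recon_post = V_healthy_post + (I_inserted − I*)/β_true`.

Step 6 makes the correction exactly invertible: applying the stage-2 formula
with the true β recovers I* to machine precision for every record,
*regardless* of the remeasurement noise, because the correction depends only
on the postoperative difference. With β̂ estimated, recovery error shrinks
as the stage-1 regression tightens (MAE ≈ 0.3 cc at n = 10⁵).

### Calibration arithmetic

- **Asymmetry.** The published summary is the mean *absolute* percentage
  difference (15.8%). Under a zero-mean normal for the signed difference,
  E|d| = σ√(2/π), so σ = 15.8·√(π/2) ≈ 19.80%. The implied exceedance
  P(|d| > 20%) ≈ 31.3% sits close to, but not exactly at, the published
  32.1% — both cannot be matched simultaneously under normality; the mean
  is matched and the exceedance is accepted as an approximation.
- **Noise SDs** invert R² = b²σ_x²/(b²σ_x² + σ_ε²):
  σ_ε = |b|σ_x√((1−R²)/R²), giving 36.56 cc (inserted) and 39.0 cc (ideal).
- **Weight correlations.** With ε_id ⟂ W,
  corr(V, W) = √R²_{ideal,W}·σ_ideal/(b_ideal·σ_V) ≈ 0.918, and the residual
  corr(ε_in, W) ≈ 0.111 absorbs what corr(V, W) does not explain of
  corr(I_inserted, W) = 0.900. Feasibility (|corr| ≤ 1 and positive
  semi-definiteness of the implied 4×4 correlation matrix) is checked and
  violations raise a calibration error naming the bound.

### Degenerate inputs and numerical choices

- Records violating positivity or the volume bounds are **resampled, never
  clamped**. Residual truncation bias: rejected records are concentrated at
  small volumes, so sample means run ~0.5% high and SDs ~1% low of the
  targets at n = 10⁵; all calibration checks use 1–2% bands that absorb
  this.
- More than 10⁴ consecutive fruitless resampling rounds abort generation.
- Moment calibration of the truncated normal is infeasible when the target
  SD exceeds the uniform-distribution limit (hi − lo)/√12; this raises a
  calibration error rather than silently drifting.
- Implant sizes are continuous by default; optional snapping to a 25 cc
  commercial grid (`implant_grid`) coarsens the inserted volume and slightly
  degrades the calibration targets, so it is off by default.
- IQRs use 25th/75th percentiles with linear interpolation; "over 20%"
  asymmetry is a strict inequality on the absolute percentage.
- One master seed feeds the generator and the bootstrap through independent
  `SeedSequence` child streams.

### What it does not emulate

- No mechanistic tissue-density link between specimen weight and breast
  volume (the ~1.06 g/mL literature density is context, not a model
  component); W is tied to V purely through the calibrated correlation.
- No demographic covariates (age, BMI), no breast-shape descriptors (width,
  height, projection, ptosis), no acellular-dermal-matrix geometry.
- The *postoperative* asymmetry distribution is a consequence of the
  inserted-minus-ideal construction, not a calibration target; its
  magnitude (mean |%diff| ≈ 30–40% at n = 56) exceeds what a real series
  would show, because every deviation of the inserted from the ideal implant
  is expressed as visible asymmetry.
- Whether real percentage differences are signed or absolute is ambiguous in
  published summaries; this generator treats the published values as
  magnitudes of a signed zero-mean quantity. A nonzero mean asymmetry
  (affected side systematically smaller) can be set via `mu_pct_asym`, but
  the default is 0 so the folded-normal calibration stays exact.

Passing tests on these cohorts therefore demonstrate that the pipeline
recovers known structure under the published moments and relations — not
that the fitted formulas generalize to other patient populations.

## Problem sizes used in the test suite

Calibration and recovery checks run on one shared 100 000-patient cohort
(seconds to generate); ground-truth-recovery comparisons use 20 cohorts of
10 000; the type-I calibration of the R² comparison uses 500 cohorts of 56
with 1000 bootstrap replicates each; the headline-direction check uses 100
cohorts of 56. Bootstrap comparisons default to 5000 replicates in analysis
runs and use 1000–2000 in tests.
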