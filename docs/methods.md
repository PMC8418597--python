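# Methods

## Scope and model

The package quantifies tumor contrast in intraoperative fluorescence images
and classifies pixels as tumor or healthy from intensity alone. Its three
statistical components are:

1. **TBR** — the ratio of mean tumor-region intensity to mean
   healthy-region intensity of one image. TBR is invariant under a global
   multiplicative gain (camera exposure) but not under an additive offset:
   adding a constant b > 0 strictly shrinks any TBR > 1 toward 1, which is
   why background subtraction upstream of this analysis would matter.
2. **Rank-sum comparison** — the unpaired Mann–Whitney test, used both for
   cohort/subgroup TBR comparisons and for pixel-intensity comparisons.
   Although such comparisons are often loosely labelled "Wilcoxon", the
   cohorts and pixel classes here are independent samples, so the unpaired
   rank-sum form is the correct one and is what is implemented.
3. **Pixel-wise logistic regression** — p(tumor) = σ(β₀ + β₁·x̃) on
   standardized intensity, with ROC validation and Youden's J selecting the
   operating point.

## Rank-sum implementation

U counts favorable pairs with ties counting ½, computed from midranks.
Small samples are handled by exact enumeration of all C(n₁+n₂, n₁) splits
of the pooled midranks; the size rule (combined n ≤ 20 or n₁·n₂ ≤ 400) is
additionally capped at 200 000 splits, because the product rule alone
admits balanced designs (e.g. 20 vs 20) whose enumeration is astronomically
large. Larger samples use the normal approximation with tie-corrected
variance and a 0.5 continuity correction. The reported z is the
tie-corrected deviate, positive when the first sample tends larger. A
normal-tail p that underflows double precision is floored at 1e-300 rather
than reported as literal zero: pooled pixel-level tests on tens of
thousands of pixels routinely produce |z| > 40, where the distinction
between "zero" and "beyond float range" matters for downstream reporting.
The empirical AUC equals U/(n₁·n₂) by construction (ties contribute ½ to
the trapezoid), and the test suite asserts this identity to 1e-12 as a
cross-check between the two code paths.

The Youden operating point (max TPR − FPR) resolves ties toward the higher
threshold, i.e. the more specific operating point; on an ROC with J ≡ 0
(identical score distributions) this returns the highest observed score.
The choice of Youden's J itself is a design decision — any ROC-based
operating-point rule would fit the pipeline — made because it is the
standard symmetric-cost rule.

## Logistic fit

Newton iteration (IRLS) with step-halving on the penalized log-likelihood;
ridge penalty λβ₁² on the slope only (λ = 1e-6 by default), which bounds
the slope on perfectly separable phantom data while leaving the intercept
free. Intensity is standardized by the training mean and SD before
fitting; thresholds are reported on the raw count scale by inverting
x* = center + scale·(logit p* − β₀)/β₁. Convergence is declared when the
largest coefficient step falls below 1e-8; hitting the 100-iteration cap
emits a warning and flags the model rather than failing. Wald standard
errors come from the inverse penalized Hessian; on separable data they are
huge, which is honest — the likelihood surface is flat there.

When the Youden threshold on the probability scale is inverted to counts,
the result is snapped onto the validation pixel intensity it derived from
(within 1e-6 relative) so that the intensity rule `x ≥ x*` and probability
rule `p ≥ p*` classify every pixel identically, including the boundary
pixel, despite floating-point round trips.

"70 % of the ground truth" is read as a stratified random 70 % of labeled
*pixels* per class: with one tumor and one healthy region per image, a
region-level split is impossible, and pixel-level stratification keeps
class balance identical between train and validation. Image-wise models
standardize per image; leave-one-image-out models standardize by their
pooled training pixels, since no shared normalization across images can be
assumed for a per-image camera exposure.

## Phantom generator

The generator emulates what the analysis assumes about the data, not tissue
optics:

- **Geometry** — a rotated ellipse of tumor inside a 128×128 (default)
  16-bit raster; the healthy ground-truth region is an annulus starting
  5 px outside the tumor boundary (10 px wide), mimicking separated expert
  contours; the ring between tumor and annulus stays unlabeled.
- **Contrast** — per-patient surface TBR is drawn from a cohort-specific
  normal truncated at 1.0 (ANGIO 3.18 ± 1.74, EPR 2.10 ± 0.92): a TBR < 1
  is not representable by the generative model, and the quoted SDs would
  otherwise permit sub-1 draws. Truncation raises the generator's *true*
  means to ≈3.53 (ANGIO) and ≈2.30 (EPR); recovery tests compare against
  these analytic truncated means, not the nominal parameters.
- **Depth** — effective contrast decays as
  TBR_eff = 1 + (TBR_surface − 1)·e^(−depth/δ) with δ = 1.3 mm. The form
  is the simplest monotone-decreasing law continuous at 0; δ is calibrated
  so that a surface TBR of ~3.2 falls below the TBR > 1.5 detectability
  reference by 4 mm depth (TBR_eff(4 mm) ≈ 1.10), reproducing the ~4 mm
  detection limit that motivates the exclusion rule.
- **Kinetics** — a two-compartment multiplier
  w·2^(−t/t_half) + (1−w)·(1 − e^(−t/τ)) with w = 0.7, t_half = 2.5 min
  (intravascular clearance of 2–3 min), τ = 20 min (EPR accumulation).
  With these defaults the multiplier at 5 min exceeds the one at 25 min,
  matching the observed angiography > EPR ordering. The multiplier
  optionally scales overall signal amplitude (`apply_kinetic_amplitude`,
  off by default); cohort *contrast* comes from the TBR draw, so amplitude
  kinetics never distorts TBR. The default is off because the TBR draw
  already encodes the timing effect and an amplitude rescale would make
  noiseless integer-exactness checks depend on rounding.
- **Noise** — Gaussian read noise (SD 400 counts) plus optional Poisson
  shot noise on the noisy mean, then clipping to the bit-depth range and
  rounding. A background mean of 5000 counts puts a TBR-3 tumor near
  1.5 × 10⁴ counts, the magnitude where published 16-bit operating points
  (~1.43 × 10⁴) live. With noise off, means are integers by default and the
  rendered TBR is exact.
- **Cohort datasets** — demographics are drawn uniformly from
  study-plausible ranges (age 34–81, BMI 19–36.6), subtype and receptor
  status from frequencies resembling a BCS population, and invasive depth
  uniformly on 0–8 mm so the depth-exclusion rule is exercised on roughly
  half the cases. Whole-specimen views render with the drawn depth
  attenuating contrast; grossed sections render at depth 0 (tumor exposed
  at the cut surface) while the metadata keeps the drawn depth.

What the phantoms do **not** emulate: within-tumor texture heterogeneity
(tumor mean intensity is homogeneous), spatial noise correlation, specular
artefacts, electrocautery damage, or multi-region contours. Passing tests
therefore demonstrate the correctness of the measurement and validation
machinery under the stated generative model, not clinical performance on
real tissue.

## Exclusion rules

Depth exclusion (strict `> 4 mm`) applies to whole-specimen ex vivo views
only; grossed sections are analyzed regardless of original depth since
grossing exposes the tumor at the imaged surface. Technical-failure and
no-tumor flags pass through from upstream. Exclusion never alters a TBR
value, only the inclusion flag — conservation the tests assert.

Subgroup dichotomies: age at 60 years, BMI at 25 kg/m², depth at the same
4 mm cut; categorical subtype/receptor strata are compared pairwise with no
multiplicity correction by default (a `holm` flag enables Holm step-down
via statsmodels when many strata are compared).

## Pipeline and determinism

`RunConfig` → generate → reload from disk (validating the I/O round trip) →
TBR + exclusions + cohort summaries + pixel-level tests → both validation
schemes → JSON + Markdown report. The config seed fans out through fixed
`SeedSequence` child keys per stage, so the whole run is a pure function of
the config; CSV outputs are written with a fixed float format and re-runs
are byte-identical. The Markdown report is rendered from the JSON dict, so
every printed number exists in the machine-readable output.

## Problem sizes

Default rasters are 128×128 (≈2 800 labeled pixels per image), a size at
which every per-image statistic is stable; tests that need ≥10⁴ labeled
pixels use 256×256 phantoms, and the 200-replicate cohort-recovery
simulation uses 64×64 phantoms, whose ≈700 labeled pixels per image leave
per-image TBR noise far below the between-patient contrast SD that
dominates that comparison.

## Known limitations

- The single-feature classifier ignores spatial context and texture by
  design; it upper-bounds what intensity alone can do.
- Exact rank-sum enumeration is capped; balanced mid-size designs fall back
  to the (tie-corrected, continuity-corrected) normal approximation, whose
  error at n₁ = n₂ = 25 is verified below 0.01 against a 10⁵-resample
  permutation oracle.
- The truncated-normal contrast model inflates cohort means relative to
  the nominal parameters (see above); nominal-mean recovery is not a claim
  the generator makes.
- Probability calibration of the classifier is out of scope; only ranking
  (ROC) and the chosen operating point are validated.
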