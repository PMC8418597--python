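# fgs-tbr

Quantitative analysis of intraoperative fluorescence images for breast
conserving surgery (BCS): tumor-to-background ratio (TBR) measurement with
clinically motivated exclusion rules, nonparametric cohort comparison, and
pixel-wise logistic-regression tumor classification with ROC validation.

The package targets the workflow of fluorescence-guided surgery (FGS)
studies using intravenous indocyanine green (ICG): patients are imaged
either shortly after injection (the *angiography* phase, ~5 min, dye still
intravascular) or later (the *EPR* phase, ~25 min, dye retained in tumor
tissue by enhanced permeability and retention), and the question is how
injection timing affects tumor contrast and pixel-level diagnostic
accuracy. Because clinical image sets of this kind are not generally
shareable, the package includes a first-class synthetic phantom generator
that emulates the relevant physics — cohort-dependent contrast, exponential
depth attenuation with a ~4 mm detection limit, ICG clearance kinetics, and
16-bit camera noise — so every stage of the analysis is testable end to end.

## The model

For an image with expert-contoured tumor and healthy regions,

```
TBR = mean pixel intensity in the tumor region
      ─────────────────────────────────────────
      mean pixel intensity in the healthy region
```

Whole-specimen ex vivo images with invasive tumor depth > 4 mm are excluded
(beyond the penetration depth of ICG fluorescence the surface signal no
longer reflects the tumor); grossed histopathology sections expose tumor at
the cut surface and are never depth-excluded. Cohorts and subgroups (age,
BMI, subtype, receptor status, depth) are compared with the unpaired
Mann–Whitney rank-sum test (midranks, tie-corrected variance, exact
enumeration for small samples).

Pixel-wise classification fits a single-feature logistic regression
`p(tumor) = σ(β₀ + β₁·x̃)` on standardized intensity x̃, validated two ways:
**image-wise** (stratified random 70 % of each image's labeled pixels train,
the held-out 30 % are scored by ROC analysis with the Youden operating
point) and **leave-one-image-out** (each image scored by a model trained on
the pooled pixels of all other images). Probability thresholds are inverted
through the model to raw camera counts, and classification overlays are
rendered as green pseudo-color on the color photograph.

## Worked example

```python
from pathlib import Path
from fgs_tbr import (PixelLogit, TBRCohortModel, apply_exclusions,
                     compute_tbr, generate_cohort_dataset, load_case,
                     validate_image_wise)

d = Path("demo")
manifest, _ = generate_cohort_dataset(10, seed=42, out_dir=d)
cases = [load_case(r, root=d) for _, r in manifest.iterrows()]
patients = {c.patient.patient_id: c.patient for c in cases}
results = apply_exclusions(
    [compute_tbr(c.image, c.mask, image_id=c.image_id,
                 patient_id=c.patient.patient_id) for c in cases],
    patients)
fitted = TBRCohortModel.from_results(
    [r for r in results if r.included], patients).fit(stratifiers=("age",))
print(fitted.summary())
```

```
TBR cohort analysis
==========================================================================
stratum                         n     mean       SD            vs        p
--------------------------------------------------------------------------
all                            20     2.43     1.08
EPR                            10     2.35     0.50         ANGIO   0.7959
ANGIO                          10     2.51     1.48           EPR   0.7959
EPR/age<60                      5     2.48     0.58   EPR/age>=60   0.4206
EPR/age>=60                     5     2.21     0.43    EPR/age<60   0.4206
ANGIO/age<60                    5     2.51     1.25 ANGIO/age>=60   0.8413
ANGIO/age>=60                   5     2.51     1.84  ANGIO/age<60   0.8413
--------------------------------------------------------------------------
```

Each row is one stratum of included images: its image count, mean ± SD of
per-image TBR, and the two-sided rank-sum p-value against its paired
stratum (with only 10 images per cohort this seed happens to draw two
similar cohorts — contrast draws have large SDs by design). Validating the
classifier on one image:

```python
score, model = validate_image_wise(cases[0], seed=0)
print(f"AUC {score.auc:.3f}, sens {score.sensitivity:.2f}, "
      f"spec {score.specificity:.2f} at {score.intensity_threshold:.3g} counts")
```

```
AUC 1.000, sens 1.00, spec 1.00 at 1.07e+04 counts
```

i.e., on this high-contrast phantom the held-out pixels separate perfectly
and the Youden operating point maps back to ≈1.07 × 10⁴ raw counts.
`PixelLogit.from_case(case).fit().summary()` prints the fitted coefficient
table in the usual model-results format.

The same stages run from the shell:

```
fgs-tbr phantom generate --n-per-cohort 20 --seed 1 --out demo
fgs-tbr tbr compute --manifest demo/manifest.csv --out demo/tbr
fgs-tbr classify run --manifest demo/manifest.csv --scheme loocv --seed 1 --out demo/cls
fgs-tbr run --config run.yaml          # full pipeline + report
```

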