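# ogttfda

Functional data analysis of 5-point oral glucose tolerance test (OGTT)
curves in youth with overweight/obesity: penalized B-spline smoothing,
functional principal components (FPCs), rule-based curve-shape
classification, cross-sectional association testing, and logistic/ROC
comparison of baseline predictors of future dysglycemia.

## The problem

A standard pediatric OGTT samples plasma glucose and insulin at 0, 30, 60,
90 and 120 minutes after a glucose bolus. Conventional summaries — fasting
plasma glucose (FPG), 2-hour glucose (2hrPG), HbA1c — discard the *shape*
of the response, yet shape (single peak vs. a dip-and-recovery vs. a
relentless rise) carries information about beta-cell function and insulin
sensitivity. This package implements two complementary shape summaries and
asks which better predicts future dysglycemia (FPG > 100 mg/dL or
2hrPG > 140 mg/dL):

1. **Manual classification** of the raw glucose series into *biphasic*,
   *monophasic*, or *monotonically increasing* using 4.5 mg/dL
   drop/re-rise rules (*inconclusive* when glucose never rises by 60 min).
2. **Functional PCA.** Each series y_i(t_j) is represented as a smooth
   curve x_i(t) = Σ_k c_ik φ_k(t) in a 7-function cubic B-spline basis with
   knots at the measurement times, fitted by penalized least squares

       ĉ_i = argmin ‖y_i − Φc‖² + λ cᵀRc,

   with R the integrated squared-second-derivative penalty and one λ per
   analyte chosen by cross-validation. FPCA then finds eigenfunctions
   ξ_1, ξ_2, ξ_3 (∫ξ_k² dt = 1, mutually orthogonal) of the covariance
   operator of the fitted curves; participant scores
   z_ik = ∫ ξ_k(t)(x_i(t) − x̄(t)) dt are standardized to mean 0, SD 1. In
   practice FPC1 tracks overall curve height, FPC2 peak timing, FPC3
   oscillation, and three components capture >99% of curve variance.

Because the motivating cohort data are restricted, the package ships a
seeded synthetic cohort generator (`ogttfda.synthetic`) reproducing the
published margins: archetype mixture 54.7/42.0/2.5/0.8%, fasting glucose
N(83, 8) mg/dL, 53.9% female, 28.8% with follow-up ≥ 6 months, and a
follow-up dysglycemia outcome (~7.3% prevalence) whose log-odds are linear
in latent curve height and the 120-min excursion — and independent of
fasting glucose by construction, so FPG is a chance-level predictor.

## Worked example

The `analysis/` drivers chain the whole study on a synthetic cohort of
n = 671 (`python analysis/01_simulate_cohort.py` through
`06_longitudinal_prediction.py`, all seeded). Representative output:

```
glucose: lambda = 4642, mean per-curve RSS = 216.99
glucose: variance explained per component [89.26  6.75  3.61] (cumulative 99.61%)
insulin: variance explained per component [93.08  3.59  2.96] (cumulative 99.62%)
68/171 pairs significant at p < 2.92e-04
  glu_fpc1 vs bmi_percentile: r = +0.25 (p = 1.2e-10, n = 670)
  ins_fpc1 vs triglycerides: r = +0.42 (p = 9.1e-30, n = 659)
in-sample AUC by predictor set:
  FPG                      0.540
  HbA1c                    0.679
  shape                    0.696
  glucose FPCs             0.807
  glucose+insulin FPCs     0.807
```

Reading this: cross-validation picked a heavy roughness penalty (five
points per curve leave little curvature to estimate); three FPCs capture
~99.6% of smoothed-curve variance per analyte; curve-height scores
correlate positively with adiposity and triglycerides (Bonferroni
threshold 0.05/171 ≈ 2.9×10⁻⁴, the 9 shape/score features × 19 metabolic
targets giving exactly 171 tests); and the FPC scores discriminate future
dysglycemia (AUC ≈ 0.81) better than shape classes (≈ 0.70) or fasting
glucose (≈ 0.54, chance level by construction of the generator).

The same stages are scriptable via the `ogttfda` CLI (`simulate`, `run`,
`smooth`, `fpca`, `classify`, `associate`, `predict`) or directly from
Python:

```python
from ogttfda import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(seed=7), n=500)
res.variance_explained   # eigenvalues and variance fractions per analyte
res.auc                  # seven-predictor AUC table
```

## Layout

- `src/ogttfda/` — library: `smoothing`, `fpca`, `shapes`, `synthetic`,
  `associations`, `prediction`, `cohort`/`config`, `pipeline`,
  `experiments`, `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — model, assumptions, numerical choices, limitations.
- `tests/` — pytest suite incl. property tests and oracle cross-checks.
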