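# Methods

## Smoothing model

Each participant-analyte series (five values at t = 0, 30, 60, 90, 120
min) is modelled as y_j = x(t_j) + e_j with x in the span of a cubic
(order-4) B-spline basis whose clamped knot vector places one knot at each
measurement time: 3 interior knots + order 4 = 7 basis functions, the only
standard choice for which "7 basis functions on 5 knots" is arithmetically
consistent. Coefficients minimize ‖y − Φc‖² + λ cᵀRc, where R is the
integrated squared second derivative (curvature) penalty, evaluated by
composite trapezoid quadrature at 1-minute resolution (configurable). The
solve uses the augmented least-squares form [Φ; √λ L] with L a symmetric
square root of R, which stays well conditioned as λ → 0; λ = 0 itself is an
underdetermined 5-equations/7-unknowns system and is answered with the
minimum-norm interpolant plus a warning, never silently.

Properties guaranteed by construction and enforced in tests: the basis is
a partition of unity; R is positive semi-definite and annihilates straight
lines, so constants and linear trends are reproduced exactly at *every* λ;
RSS is nondecreasing and roughness cᵀRc nonincreasing in λ.

### Penalty selection

The paper-level procedure uses a single λ per analyte, not per
participant. λ is chosen on a log-spaced grid (1e−4 … 1e4, 25 points) by
leave-one-point-out cross-validation pooled over all participants: each
timepoint is deleted in turn, curves refitted from the remaining four, and
the deleted value predicted; identical designs across participants reduce
each deletion to one linear solve for the whole cohort. GCV would be a
defensible alternative; LOO-CV was chosen because it matches the
five-point structure directly and needs no effective-degrees-of-freedom
approximation. A flat CV profile (e.g. a cohort of straight lines, which
every λ reproduces) is flagged and resolved to the *largest* grid value —
maximal smoothing is free when the data carry no curvature signal;
genuinely distinct scores tie-break to the smallest λ.

## Functional PCA

Fitted curves live in the 7-dimensional basis span, so the covariance
operator reduces to the coefficient covariance Cov(c) seen through the
Gram matrix J = ∫φφᵀ dt. Writing an eigenfunction as ξ = φᵀb, the operator
eigenproblem becomes the symmetric matrix problem
J^{1/2} Cov(c) J^{1/2} u = λu with b = J^{−1/2}u, whose eigenvalues are
exactly the FPC score variances. This coefficient-space route is the
implementation; a brute-force eigen-decomposition of the grid-discretized
covariance (121-point grid, trapezoid weights) serves as an independent
oracle in the tests, and the two agree to |cosine| ≥ 0.999 and eigenvalue
relative error ≤ 1e−4.

Choices worth stating:

- **Centering.** Scores integrate ξ_k against the *mean-centered* curve.
  An uncentered convention would shift every score by the same constant,
  which the subsequent standardization (mean 0, SD 1, n−1 denominator)
  erases; downstream results are identical either way.
- **Sign convention.** Eigenfunctions are sign-ambiguous; each ξ_k is
  flipped so ∫ξ_k dt ≥ 0, falling back to ξ_k(0) > 0 when the integral is
  below 1e−9. This makes FPC1 "higher curve → higher score" and makes runs
  reproducible.
- **Three components, fixed.** The number of retained components is a
  design constant (3), not data-adaptive; variance-explained fractions are
  reported against the total over all (≤ 7) components.
- **Quadrature.** Every inner product uses the same composite trapezoid
  rule as the penalty, so coefficient-space score computation and direct
  quadrature of ξ·(curve − mean) agree exactly, not just approximately.

Quartile/decile curve summaries bin participants by per-component score
quantiles (ties to the lower bin) and average the fitted curves per bin.

## Shape classification

The classifier operates on the raw measurements, not smoothed curves,
since the manual procedure it reproduces reads observed profiles. Rules,
applied in a fixed order that makes the labels mutually exclusive and
exhaustive: (a) *inconclusive* — no rise strictly above the fasting value
at 30 or 60 min; (b) *monotonically increasing* — no point more than
δ = 4.5 mg/dL below the running maximum (strict >, honouring "more than");
(c) *biphasic* — after the initial peak (first running maximum later
undercut), some later point at least δ below it followed by a rise of at
least δ from that minimum (inclusive ≥, honouring "at least");
(d) *monophasic* otherwise. Plateaus count as neither rise nor drop. An
exhaustive small-integer-lattice enumeration against an independent
brute-force rule checker verifies that raising δ moves labels only along
biphasic → monophasic → monotonically increasing.

## Synthetic cohort generator

The generator exists so every stage is testable without the restricted
study data. It emulates: the archetype mixture (monophasic 54.7%,
biphasic 42.0%, monotonic 2.5%, flat 0.8%), fasting glucose N(83, 8)
mg/dL, demographic margins (53.9% female, ages uniform 8–18, BMI
percentile 85 + 15·Beta(4, 1.1), median ≈ 97), 28.8% follow-up fraction,
and a follow-up dysglycemia prevalence calibrated to 7.3%.

Archetype mean curves are monotone piecewise-cubic (PCHIP) bumps through
control points chosen so each archetype triggers its own classifier rule
deterministically at zero noise: the monophasic bump peaks at 45–75 min
(uniform peak-time jitter feeds FPC2) and returns toward baseline; the
biphasic curve peaks at 30 min, dips 40–50% of its amplitude and re-rises
22–30%; the monotonic curve increases through 120 min; the flat curve is
constant. Amplitudes are lognormal around archetype-specific means
(60/40/75 mg/dL) with floors that keep the zero-noise classification
guarantee, and are positively coupled to BMI percentile. Insulin is a
gain-and-delay transform of the glucose excursion — insulin(t) =
gain·(basal + scale·exc(t − delay) + noise) — rather than an ODE model: no
mechanistic claim is made, and FPCA only needs realistically correlated
curves. The per-participant gain is lognormal and BMI-linked (insulin
resistance). Measurement noise defaults: glucose 4 mg/dL (assay plus
short-term biological variability at 30-min sampling), insulin 4 μU/mL on
the pre-gain scale, so effective insulin noise scales with curve height
like a constant-CV assay. No published insulin summary statistics were
available to anchor the insulin noise scale; it is a free calibration
choice.

Metabolic labs (HbA1c, triglycerides, HDL/LDL, blood pressure, waist) are
linear-in-latent-height (plus gain, for lipids) with noise, calibrated so
Spearman correlations with the FPC1 scores land in the 0.15–0.5 band — a
calibration target, not ground truth. Small per-variable missingness
(BP 3.1%, waist 3.6%, lipids 1.5%) exercises the complete-case paths.

The outcome model draws the follow-up dysglycemia indicator from a
logistic whose linear predictor uses the standardized latent curve height
and the latent 120-minute excursion *above fasting* (coefficients 0.9 and
0.7; intercept −3.35 calibrated once at large n for 7.3% prevalence).
Using the excursion rather than raw 120-min glucose keeps the outcome
independent of fasting level, so FPG is a chance-level (AUC ≈ 0.5)
predictor by construction — the structural feature the predictor
comparison is designed to detect. Follow-up FPG and 2hrPG are then drawn
conditionally on the indicator (FPG from the same bounded distribution in
both arms; 2hrPG above/below 140 mg/dL), so the composite label rule
reproduces the indicator exactly. A single master seed spawns one
substream per participant; enlarging a cohort never perturbs existing
participants.

What the generator does *not* emulate: pubertal-stage effects, joint
demographic structure beyond the published margins, within-participant
OGTT reproducibility, assay-specific error structure. Passing tests
therefore demonstrate the pipeline's statistical machinery and its
behaviour under the stated latent structure — not clinical performance on
real cohorts.

## Statistical procedures

- **Spearman battery.** 9 curve-summary features (3 shape dummies + 6
  standardized FPC scores) × 19 targets (10 timed glucose/insulin values +
  9 labs) = 171 correlations, matching the analysis design's multiplicity
  constant; the Bonferroni flag fires at 0.05/171 ≈ 2.92e−4. The
  comparison count is a configuration constant, not recomputed from data.
  p-values use the t-approximation for n > 10 and an exact permutation
  enumeration (all n! pairings, vectorized in chunks) for n ≤ 10.
  Undefined pairs (constant columns) are reported as NaN and never
  flagged.
- **Group differences.** Kruskal–Wallis for continuous variables across
  shape classes; Fisher's exact test for categorical ones (scipy's exact
  2×2; a seeded Monte-Carlo permutation version of the exact test for
  r×c tables).
- **Adjusted models.** OLS of each FPC score on one lab exposure plus
  age, sex, race, ethnicity (reference-coded). Complete cases per model;
  rank-deficient designs are rejected naming the aliased columns.
- **Longitudinal.** Paired Wilcoxon signed-rank for continuous change;
  McNemar for the dysglycemia rate (exact binomial when discordant pairs
  < 25, uncorrected chi-square otherwise — ten conversions against ten
  remissions yields p = 1.000 exactly). Seven predictor sets (FPG, 2hrPG,
  HbA1c, shape dummies with monophasic as reference, glucose FPCs, insulin
  FPCs, both) are fitted by unpenalized ML logistic regression;
  *in-sample* predicted probabilities feed the ROC, matching a
  small-cohort design with no train/test split. AUC is the Mann–Whitney
  concordance (ties = ½), verified against an all-pairs oracle to 1e−12.
  Separation (likely with ~14 events) is detected and answered with a
  flagged, weakly ridge-stabilized score that preserves the separating
  ranking; it is never silent.

## Numerical and design notes

- In-sample AUC of a *fitted* model is optimistically biased: a univariate
  logistic folds the direction of its feature (AUC ≥ 0.5 always), and a
  p-feature fit inflates AUC by roughly √p × the null AUC standard
  deviation. The replicate study therefore scores single-lab predictors by
  the raw variable's concordance in its natural risk direction (identical
  to the fitted model's discrimination by monotonicity of the link), and
  unit tests use feature-count-scaled null bands.
- Replicate experiments (`ogttfda.experiments`) use 500 cohorts of n = 200
  with universal follow-up for the predictor-ordering study and n = 500
  for the variance-capture figure — sizes chosen to keep each replicate's
  event count near the motivating study's (~14) while giving stable
  medians.
- Degenerate inputs fail loudly: identical curves (zero covariance), too
  few curves for the requested components, zero-variance score components,
  single-class outcomes, all-constant predictor sets (answered with a flat
  probability, AUC exactly 0.5).

## Known limitations

- Whether the original analysis used GCV or k-fold CV, and whether its
  knots coincided exactly with measurement times, is unknowable from the
  text; both decisions here are explicit and configurable.
- The exact inventory behind the 171-comparison constant is a design
  reconstruction (it falls out naturally as 9 × 19).
- No shape-constrained smoothing, no per-participant λ, no bivariate
  glucose+insulin FPCA (analytes are decomposed separately), no confidence
  intervals or DeLong tests on AUC differences, and no external-cohort
  validation.
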