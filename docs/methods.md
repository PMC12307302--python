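# Methods

This note documents the statistical procedures the package implements,
the design decisions taken where more than one reasonable reading
existed, what the synthetic cohort generator does and does not emulate,
and the numerical choices that make results bit-reproducible.

## Normative adjustment (residual method)

Baseline regional volumes are adjusted for head size and age by ordinary
least squares on the design `[TIV², age², TIV·age, TIV, age, 1]` — six
coefficients (a–f). The quadratic terms capture the accelerating,
non-linear age effect on hippocampal volume in elderly cohorts; a
`model="linear"` option restricts the design to `[TIV, age, 1]` for the
classical linear residual method. Which variant a given study used is
often ambiguous; both are first-class here and neither is asserted as
canonical. Age is always age at the first scan.

The residual (observed − fitted) is converted to a z-score by subtracting
the cohort mean residual (zero, since an intercept is fit) and dividing
by the sample SD (ddof = 1 throughout the package; this matters at
n ≈ 200 and is fixed so results reproduce exactly).

**Two-pass exclusion.** Subjects with |z| strictly greater than 3 in
either hemisphere after pass 1 are removed subject-wise (the analysis
removes individuals, not hemisphere observations), and the fit,
residuals and standardization are recomputed on the retained sample.
Exclusion uses the pass-1 z-scores once — the procedure is not iterated.
Hemispheres are modelled independently (separate fits and reference
distributions). Under Gaussian residuals the false-exclusion rate is
2·Φ(−3) ≈ 0.27% per subject-hemisphere, which the test suite checks
empirically.

**Conditioning.** TIV² spans ~10¹² mm⁶ while the intercept column is 1,
so the solver centers and scales TIV and age internally, solves by SVD
least squares with an explicit rank check (a rank-deficient design
raises an error rather than silently taking a pseudo-inverse), and
back-transforms the coefficients to the raw scale for reporting. The
oracle-equivalence tests against an explicit normal-equations solve are
run with covariates at O(1) scale, where that oracle is itself
numerically valid; correctness at realistic mm³ scale is established by
parameter recovery against known generating coefficients.

## Annualized percent change

`APC = 100 · (V₂ − V₁)/(V₁ · Δt)` on raw absolute volumes (never on
adjusted or z-scored values), with the inter-scan interval as decimal
years per subject. This is a two-point linear annualization; it does not
model curvature of individual trajectories, and no multi-timepoint
fitting is offered. Note that the APC of cohort-mean volumes is not the
cohort mean APC (a ratio of means is not a mean of ratios); the test
suite pins the distinction with a hand-computed example.

## Continuous Cognitive Score

Every test is standardized against the **baseline** cohort mean/SD of
that test; follow-up scores use the same baseline reference, which is
the only convention under which "change of at least 0.5 SD at follow-up
compared to baseline" is well defined without external norms. Tests
where a lower raw score is better (e.g. timed trail-making) must be
declared in an orientation map and are sign-flipped before
standardization. Thresholds are inclusive (≥ +0.5 improves, ≤ −0.5
declines); a test missing at either assessment contributes to neither
count and the per-subject count of usable tests is reported. The CCS is
improved − declined per follow-up; total change sums the 18- and
54-month scores, giving a range of ±2·n_tests.

## Inference

* **Correlation.** Pearson r with a one-tailed t-test on n−2 df. The
  headline direction is positive: lower baseline z ⇒ more negative APC.
* **Regressions.** APC per hemisphere on baseline z (one-tailed,
  positive), sex (female = 1), age, education dummies for 9–12 y and
  > 12 y (reference < 9 y), APOE-ε4 carriage, and optionally amyloid
  positivity. Coefficients are unstandardized; confidence intervals are
  two-sided 95% regardless of the p-value's tail; for a term with
  positive t, the one-tailed p is exactly half the two-tailed p.
  Complete-case analysis only — adding amyloid shrinks n to the PET
  subset; no imputation is performed, and no multiple-testing correction
  is applied across hemispheres or models (the report footer says so).
  The fits are computed through statsmodels OLS behind the package's
  interface; the test suite verifies them against an explicit
  normal-equations + t/F oracle.
* **MCAR test.** Little's (1988) chi-square: the grand mean and
  covariance are estimated by EM under a multivariate-normal model, and
  the statistic sums, over missingness patterns j,
  n_j·(x̄_j − μ_obs)ᵀ Σ_obs⁻¹ (x̄_j − μ_obs) on Σ_j p_j − p degrees of
  freedom. "An MCAR test" is ambiguous in common usage; Little's test is
  the standard referent and is what is implemented (by hand — no
  dependency ships it). EM runs to a 1e-6 relative tolerance, max 200
  iterations, with a tiny diagonal ridge on the starting covariance.
  Applicability requires at least two missingness patterns.
* **CCS regression.** Total cognitive change on baseline z, two-tailed.
  A constant response yields slope 0 and R² reported as 0 with a
  warning rather than NaN.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline is
calibrated against: n = 182; age at baseline 73.4 ± 3.5 y truncated to
68–85 y (the truncation-adjusted location is solved so the realized mean
is 73.4); interval 4.8 ± 1.0 y (truncated below at 0.5 y); 59.3% female;
education 14.4 / 45.6 / 40.0% across < 9 / 9–12 / > 12 y; 16.7% APOE-ε4
carriers; amyloid positive in 24.3% of assessed subjects with 79/182
missing completely at random; ICV 1.45 ± 0.14 × 10⁶ mm³ (a typical
FreeSurfer eTIV scale; the source cohort's value is not published).
Baseline volume is the normative model (defaults: a linear TIV/age
surface with d = 0.0012, e = −35 mm³/y, intercepts chosen to give
cohort means 3653.37/3766.93 mm³ left/right) plus a subject residual
(SD 316 mm³, chosen so the total baseline SD lands near the reported
~380–400 mm³ once TIV and age variation are added).

True APC per hemisphere is drawn jointly with the baseline residual from
a bivariate normal — means −1.79/−1.34, SDs 1.00/0.94 %/y left/right,
correlation `rho_baseline_apc` (default 0.16, between the two published
hemisphere estimates) — which is the simplest structure consistent with
a Pearson-correlation analysis. Follow-up volume is
`V₂ = V₁·(1 + APC/100·Δt)` (linear-in-time fractional loss, matching the
linear annualization of the APC definition; a compound-decay variant
sits behind `volume_change="compound"`). Independent measurement noise
(default SD 30 mm³, the order of FreeSurfer longitudinal test–retest
error for the hippocampus) is added to both observed timepoints after
the latent trajectory, so tests can probe attenuation. Left and right
residuals are drawn independently; real hippocampi correlate strongly
across hemispheres, but no downstream stage pools them, so the
simplification is inconsequential here.

The battery is emulated as 14 exchangeable standardized scores (real
instruments are heterogeneous and unpublished per-test): baseline ~
N(0,1); each follow-up adds a per-subject drift shared across tests
(−0.1 ± 0.25 z per follow-up) plus independent test-retest noise
(0.8 z). With these values the cohort mean total cognitive change is
≈ −2 (SD ≈ 5): the same sign and order as published healthy-elderly
composites, though somewhat more negative than the −1.1 (4.1) scale the
drift was modelled after — matching that value exactly would require
test-retest noise near 2 z (reliability ≈ 0.2), which no real battery
has. The calibration test therefore asserts sign and order of magnitude,
not the exact composite mean.

Randomness: one master seed spawns fixed, named sub-streams
(demographics, volumes, battery, missingness, battery-drift), so adding
a stage never perturbs earlier draws, and identical parameters give
bit-identical tables. MCAR missingness blanks exactly `round(rate·n)`
cells chosen uniformly, independent of all covariates.

What the generator does **not** emulate: scanner or segmentation
effects (no inter-scanner shift between timepoints), cross-hemisphere
residual correlation, non-Gaussian volume distributions, practice
effects or floor/ceiling in the battery, and any dependence of amyloid
or APOE on volumes (covariate effects on APC are zero by construction).
Passing tests therefore demonstrate the pipeline's correctness and
calibration under its own assumptions — not that real cohorts satisfy
those assumptions.

## Problem sizes used in validation

Marginal calibration and parameter recovery use cohorts of 5,000–10,000
subjects (coefficient recovery to < 2% relative error uses n = 10,000
with residual SD 50 mm³ so every coefficient's signal comfortably
exceeds its standard error); correlation-injection checks average 1,000
replicates at the cohort's own n = 182; test calibration uses 5,000
null replicates (type-I error and Little's test at n = 200 with 30%
missingness) and 2,000 replicates for the power anchor at r = 0.17,
n = 182, compared against the Fisher-z closed form
Φ(atanh r·√(n−3) − z₀.₀₅) ≈ 0.74.

## Known limitations

Two-point APC cannot separate measurement error from true change;
regression to the mean contributes to the baseline-z/APC association in
real data and is not modelled here. The normative model fits the study
sample itself (no external normative database), so z-scores are
relative to the cohort, not the population. Education is ordinal but
entered as dummies; sex enters only as a covariate, not in the
normative model. The MCAR test assumes multivariate normality of the
quantitative variables it screens.
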