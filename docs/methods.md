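# Methods

`metscate` estimates how a calendar-time exposure — having one's follow-up
health checkup fall in the first pandemic fiscal year rather than a
pre-pandemic year — changed the probability of new-onset metabolic
syndrome (MetS), and how that change varies across people.  This note
describes the model, the estimator, the synthetic data used to validate
it, the numerical choices, and the estimator's known limitations,
including one that matters a great deal in practice.

## Estimand and causal assumptions

For covariates `X = x`, the conditional average treatment effect is the
risk difference

    tau(x) = E(Y^1 - Y^0 | X = x),

where `Y^1`, `Y^0` are potential new-onset-MetS outcomes with and without
pandemic-year exposure.  Identification rests on three assumptions:
(1) the measured checkup covariates suffice to predict the potential
outcomes; (2) the outcome mechanism given covariates is stable across the
study years; (3) exposure is independent of baseline covariates — nobody's
lab values influenced whether their follow-up fell in the pandemic year.
Assumption (3) is why the blending weight below is the *marginal* exposure
probability `g = n_exposed / n_total` rather than a propensity score.

## The X-learner estimator

1. **Outcome models.**  Logistic regressions `M0` (unexposed arm) and
   `M1` (exposed arm) predict the binary outcome from the design matrix.
   Candidate feature sets (original columns; plus squares; plus pairwise
   interactions over a shortlist) are compared by pooled out-of-fold AUC
   in a 10-fold stratified cross-validation and the best is kept.
2. **Imputed treatment effects (ITE).**  Each record gets a pseudo-effect
   from the opposite arm's model: `d1 = Y - M0(x)` for exposed records,
   `d0 = M1(x) - Y` for unexposed records.  Values lie in [-1, 1]:
   -1 is certain prevention, +1 certain causation.
3. **Effect models.**  The ITEs are rescaled to (0, 1) via
   `(d + 1) / 2` (with boundary compression, below) and modelled by beta
   regressions `M2` (unexposed) and `M3` (exposed) with a logit mean link
   and one scalar precision `phi` (log link).  Feature sets are selected
   by pooled out-of-fold RMSE, 10-fold unstratified CV.
4. **Blend.**  Predictions are back-transformed, `tau_k = 2*mu_k - 1`, and
   combined as

       cate(x) = g * tau0(x) + (1 - g) * tau1(x).

   The direction — `g` multiplying the unexposed-side model — follows the
   standard meta-learner convention; the swapped variant is available via
   `PipelineConfig(swap_weights=True)` and the convention used is recorded
   in the result metadata.

**Bootstrap inference.**  Records are resampled with replacement within
each exposure arm (so `g` is preserved exactly), the pipeline reruns per
replicate with feature sets frozen at the original-sample selection, and
each statistic (overall mean, subgroup means, between-group differences)
gets percentile 2.5/97.5 bounds and a two-sided sign-fraction p-value
`2 * min(frac <= 0, frac >= 0)`, floored at `1/n_boot`.  The default
`n_boot` is 15,000; tests and examples use reduced counts.  Re-selecting
feature sets inside every replicate would multiply cost by the number of
candidates and is not done.  Percentile intervals from this bootstrap are
known to run narrow for X-learner estimates; coverage near, but not at,
the nominal level should be expected.

## The MetS classifier

Japanese (MHLW) criteria: excess visceral fat — waist >= 85 cm (male) /
>= 90 cm (female) — **and** at least two of: triglycerides >= 150 mg/dL or
HDL < 40 mg/dL; blood pressure >= 130/85 mmHg; fasting glucose
>= 110 mg/dL.  All thresholds use `>=` except HDL (`<`).  Each factor is
tri-state (positive / negative / indeterminate); the verdict is
`indeterminate` exactly when the unresolved factors could still swing the
2-of-3 decision, which the test suite verifies against brute-force
enumeration of every flag/missingness combination.  Casual (non-fasting)
glucose is non-diagnostic by default; when fasting glucose is absent an
HbA1c >= 6.0 % (NGSP) substitution may resolve the factor.  Both branches
are configurable (`GlycemiaRule`) because screening programmes differ
here, and the defaults should not be read as any particular programme's
exact flowchart.  Indeterminate verdicts are meant to be excluded from
outcome analyses.

## Preprocessing

Continuous variables: single median imputation (medians over the pooled
analysis sample) with one 0/1 missingness indicator per imputed column.
Categoricals: one-hot with an explicit `missing` level, most frequent
level dropped as reference.  Exactly duplicated, complementary (for 0/1
columns) and constant columns are pruned — complementary missingness
flags of an exclusive fasting/casual lab pair are otherwise perfectly
collinear with the intercept.  Interactions default to pairs among
`age, bmi, waist, sbp, hdl`; unrestricted pairwise expansion over ~50
columns is combinatorially wasteful and mostly collinear.

## The synthetic cohort generator

The generator is the package's ground-truth instrument: it emulates the
checkup schema (anthropometry, blood pressure, urinalysis ordinals, blood
chemistry with mutually exclusive fasting/casual triglyceride and glucose
channels, sparse HbA1c, ~99.8 % missing urinary occult blood), two arms of
2,181 / 1,391 records with realistic per-arm drift (sex mix 70.8 % vs
62.3 % female, fasting fraction 16 % vs 25 %, HbA1c availability 48 % vs
97 %), and an additive-risk outcome:

    Y ~ Bernoulli( p0(x) + E * tau(x) ),

with the true `tau(x)` stored per record.  Configs whose realized risk
leaves [0, 1] are rejected.

The default baseline risk `p0` is a bounded sigmoid in age, sex, BMI,
waist and treatment history: floor 0.002, ceiling 0.82, slope and
intercept calibrated once so the unexposed-arm onset rate is ~3.0 % and a
10-fold CV AUC of ~0.93 is attainable — the strongly discriminative
regime this estimator is designed for.  The 0.82 ceiling is forced by the
additive model: with subgroup effects up to ~0.154 the baseline must
leave headroom, which also caps the attainable AUC slightly below the
mid-0.9s.

Three effect-surface presets cover the interesting conditions:
`table1` (constant tau = 0.022, so the two arms show ~3.0 % / ~5.2 %
onset), `table3` (department step: administrative 0.034, research 0.068,
medical 0.032, intensive care 0.154; cohort mean ~0.044), and `null`
(tau = 0).  The constant-tau and department-step presets cannot both hold
in one cohort: with exposure independent of covariates, the true mean tau
*is* the expected arm-rate difference, so a mean effect of 0.044 is
incompatible with arm rates 3.0 %/5.2 %.  Each validation uses the preset
that defines its condition.

An anonymization emulator reproduces the de-identification mechanics of
shared checkup data: Gaussian noise on continuous quasi-identifiers
(default sd = 5 % of each field's sd — a placeholder magnitude, since
only the mechanism, not its scale, is public), resampling with
replacement, and regeneration of record identifiers.

What the generator does **not** emulate: within-person correlation across
baseline years (de-identification largely destroys it anyway), real
biochemical correlation structure between labs (labs are drawn
independently given the arm), and department-specific covariate profiles.
Passing recovery tests on this generator therefore shows the estimator
handles the schema, the missingness structure and the outcome model — not
that it is robust to every dependence pattern of real checkup data.

## Numerical choices

* **Separation fallback.**  Rare outcomes over ~50 columns quasi-separate
  (urine-ordinal dummies with a handful of rows can take coefficients
  > 30 even when IRLS "converges").  When plain maximum likelihood fails
  or produces such coefficients, the logistic fit is redone with a weak
  fixed L2 penalty on standardized columns (inverse strength `C = 1e4`)
  and flagged `ridge_fallback` in the fit and in pipeline metadata.
* **Boundary compression.**  Rescaled ITEs are clamped to
  `[0.5/n, 1 - 0.5/n]` before the beta fit.  At exact endpoints this
  equals the usual `(y*(n-1)+0.5)/n` compression; it also catches values
  that float saturation pushed within machine precision of a boundary,
  where the beta log-likelihood otherwise explodes.
* **CV scoring.**  One pooled out-of-fold score per candidate (not a
  per-fold average): well-defined down to leave-one-out and verified
  against a brute-force LOO oracle.  Ties within 1e-6 go to the smaller
  feature set.  Stratified folds for the binary outcome (k lowered to the
  minority-class count when needed); plain k-fold for the effect models.
* **Degenerate inputs.**  Single-class labels, empty arms, all-missing
  continuous columns, invalid `g`, undersized decile splits and
  sub-minimum `n_boot` all raise immediately with named messages.

## Calibration, and a bias every user should know about

Two facts, both verified by the test suite at n = 10,000:

* **Under the null the estimator is clean.**  With `tau = 0` the mean
  overall CATE across 20 seeds is ~0.0005, and swapping the arm labels
  negates every per-record estimate exactly (an algebraic symmetry of the
  pipeline: roles flip, beta fits map through `y -> 1 - y`).
* **Non-zero constant effects are amplified roughly two-fold.**  A true
  constant `tau = 0.05` is recovered as ~0.10; a department step (0.03 /
  0.15) keeps its ordering — the intensive-care group is always ranked
  highest — but the levels are inflated by a similar factor.

The amplification is a property of the *method*, not an implementation
artifact: the independent numeric-MLE oracle reproduces the fitted beta
parameters to 1e-6.  The root cause is that the beta distribution is an
exponential family in `(log y, log(1-y))`, so a beta-regression MLE
matches logarithmic moments rather than the mean.  With a rare binary
outcome the rescaled pseudo-effects are a near-two-point mixture — bulk
mass just below 0.5 and a small spike near 1 for the records whose
outcome the opposite-arm model could not anticipate — and the spike's
`log(1-y)` leverage drags the fitted mean far beyond the mixture mean.
The effect grows as the outcome models get *more* discriminative, because
their confident predictions push the spike closer to the boundary.  Under
the null the two arms' spikes are symmetric and cancel in the blend;
under a genuine effect they do not.  A mean-targeting second stage
(least squares, or a quasi-likelihood with identity-variance weighting)
would not have this property; beta regression is retained here because it
is the method under study.  Consequently: treat subgroup *rankings* and
null/non-null conclusions as meaningful, and treat absolute CATE levels
from this estimator as upper-end figures.

## Problem sizes used in validation

Calibration and recovery suites run 20 (null) and 6 (recovery) cohorts of
n = 10,000 with the single `original` feature set; CV selection, bootstrap
mechanics and coverage smoke-checks run on cohorts of 500–1,500 records
with 100–200 bootstrap iterations.  The reproduction script
(`scripts/acceptance.py`) runs the full CV pipeline at the study size
(n = 3,572) plus a five-seed null diagnostic at n = 10,000.

## Known limitations

* The amplification bias above; it dominates every other error source.
* Percentile bootstrap CIs are anti-conservative for this estimator.
* Median imputation plus indicators is simple and auditable but can bias
  coefficients when missingness is informative beyond the indicator.
* The generator draws labs independently given the arm; estimators that
  exploit lab–lab correlation are not stress-tested here.
* International (IDF/NCEP) MetS criteria and the rib-crest waist
  convention are documented differences, not implemented options.
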