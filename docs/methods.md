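# Methods

## The model

`metastack` implements stacked generalization for clinical risk prediction
with two deliberately heterogeneous base-learners:

1. **Penalized spline regression** ("ridge"): an L2-penalized linear
   (continuous outcome) or logistic (binary outcome) model whose design
   expands each of the three continuous predictors — age, BMI, baseline
   depression severity — into a 4-knot restricted cubic spline basis.
   With knots t1 < t2 < t3 < t4 the basis contributes k−1 = 3 columns: the
   identity and two truncated-cubic combinations constrained to be linear
   beyond the boundary knots. Knots sit at the 0.05/0.35/0.65/0.95
   quantiles of the training values (the Harrell convention); the
   nonlinear columns are divided by (t4−t1)² so they share the scale of
   the linear term under the common penalty. Categorical predictors are
   one-hot encoded with no reference level dropped (the penalty absorbs
   the collinearity); the intercept is never penalized. The penalty is
   chosen by internal 5-fold cross-validation over a 25-point log grid
   from 1e−4 to 1e4.

2. **Multi-layer perceptron**: 3 hidden layers × 256 ReLU units, squared
   error (continuous) or cross-entropy with sigmoid output (binary),
   adaptive-moment optimization, batch size 256, at most 100 epochs with
   early stopping on a 10% internal validation split (patience 10), small
   conventional weight decay (1e−4), inputs standardized internally. The
   exact training recipe is an open choice; these are stated defaults so
   every run is reproducible, and all widths/depths are configurable.

### Out-of-bag stacking

The meta-learner must never see a base prediction produced by a model
whose training data contained that patient. For each of the m imputed
datasets we draw B bootstrap samples (size n, with replacement) of the
outcome-observed patients, fit both base-learners on each sample and
predict only on its exact out-of-bag complement. Defaults m=10, B=20 give
200 fits per learner. Predictions are accumulated per (patient, learner)
and averaged across all m×B replicates — pooling over both imputations
and bootstrap replicates — into exactly one meta-feature row per patient.
A patient who lands inside every bootstrap sample (probability
≈ 0.632^(mB), negligible at defaults) is excluded from meta-training with
a warning rather than refitted, preserving the leakage guarantee. The
out-of-bag invariant is asserted structurally on every run and audited in
tests by replaying the per-plan prediction logs.

Two meta-learners take the two averaged prediction columns as their only
default inputs: an **unregularized** linear/logistic regression, and an
MLP of the same 3×256 shape. Because the linear meta-learner must remain
unpenalized, perfect collinearity between the prediction columns is
resolved by minimum-norm solutions: least squares via `lstsq` for the
continuous task and IRLS with pseudo-inverse Newton steps for the binary
task (cross-checked in tests against an unpenalized scikit-learn fit).
Patient covariates can optionally be appended to the meta inputs, one
numeric column per covariate (categoricals as integer level codes, so 31
covariates plus 2 predictions give 33 columns).

### Multiple imputation

Missing predictors are completed by chained equations: each incomplete
variable is regressed on all other predictors **and both outcome columns**,
continuous variables entering every imputation design through the same
4-knot restricted splines as the analysis model. Continuous targets are
filled by predictive-mean matching (one draw from the 5 nearest donors by
predicted mean); binary/categorical targets by a draw from
multinomial-logistic class probabilities. Each of the 5 cycles refits on a
bootstrap resample of the observed rows so imputations are proper.
Outcomes are imputed internally only so they can serve as predictors; the
returned datasets keep the outcomes' original missingness, and every
downstream fit and evaluation is restricted to patients with an observed
outcome. Copy j runs on the seed stream of seed+j. Default m=10.

### Evaluation

* Continuous outcome: MAE. Binary outcome: AUC (Mann–Whitney, ties ½)
  and calibration-in-the-large (mean predicted probability minus observed
  event rate; no recalibration).
* Base-learner point estimates are the mean of the m×B per-replicate
  out-of-bag values; intervals are 2.5th–97.5th percentile bootstrap
  intervals with the linear-interpolation quantile rule (fixed so CI
  endpoints are bit-reproducible).
* Meta-learner uncertainty: a row-resampling bootstrap of the meta-feature
  table (default R=200); each resample refits both meta-learners and
  scores them on its out-of-bag complement.
* Reported comparisons: plain relative change for MAE; for AUC the chance
  level 0.5 is subtracted from both values before the relative change, so
  gains are expressed as a share of discrimination above chance. From
  rounded values 4.63→4.52 gives +2.38% and 0.598→0.604 gives +6.12%.
* Permutation feature importance: sample 10 trained bootstrap models
  without replacement, shuffle each predictor of each model's own
  out-of-bag data 100 times, record the percent change of MAE or raw AUC
  (oriented so larger = more important), average over shuffles then over
  models. Shuffling operates on the design-matrix block of the feature,
  which is mathematically identical to shuffling the raw column and
  re-applying the frozen transform, and much faster. The same algorithm on
  the meta input columns measures each base-learner's contribution.
* Internal–external cross-validation: leave one data-collection region
  out, develop *everything* — imputation models, knots, scalers, all
  base and meta fits — on the remaining regions, impute the held-out
  region from the frozen training imputers (single seeded draw per copy),
  score all four models on its outcome-observed patients, and report
  per-region values plus the unweighted across-region mean. Whether to
  refit imputation per fold was an open design point; refitting is the
  conservative choice and is what the leakage tests assert.

## The synthetic cohort generator

The real development data (a UK primary-care extract of ~188k patients
with depression starting an antidepressant) are access-restricted, so the
package ships a generator that emulates their structure: 31 predictors —
age (Uniform 18–90), BMI (Normal 27.5, 5, clipped 15–45), baseline PHQ-9
severity (Normal 16, 5, clipped 0–27), 20 binary comorbidity/demographic
flags and 8 categoricals with realistic marginals; ten regions with
Gaussian random-intercept heterogeneity (default SD 0.3, deliberately
small); a PHQ-9 outcome built from a linear predictor dominated by
baseline severity (0.5 points per baseline point) plus a smooth cubic
bend in severity and a severity×age interaction (both with configurable
weights, so purely linear and strongly nonlinear regimes are both
reachable), region effect and Gaussian noise (SD 5), rounded and clipped
to 0–27; and a binary dropout outcome from a weak logistic model led by
ethnicity and deprivation, whose intercept is calibrated by root-finding
so the population event probability equals 37.5% exactly.

Missingness is missing-at-random by construction: the probability of
masking baseline severity (rate 0.75) depends only on age and two fully
observed flags, BMI masking (0.10) on sex, with intercepts calibrated to
the target rates; one categorical (alcohol use) is masked completely at
random at 0.05. The continuous outcome is observed for an
8.73% subset (16,384/187,757), masked completely at random. The generator
returns the full ground truth (conditional means before and after
clipping, event probabilities, coefficients, region effects) for recovery
tests.

What the generator does **not** emulate: realistic correlation among
predictors (they are drawn independently), clinical coding systems,
informative observation times, or non-random outcome ascertainment.
Passing tests therefore demonstrate that the machinery is correct and
that stacking behaves as expected under known signal mixtures — not that
the real-data performance figures transfer.

## Numerical choices and degenerate inputs

* One master integer seed fans out into named per-stage streams (CRC32 of
  the stage name into a `SeedSequence`), so any stage is independently
  reproducible and seeds handed to scikit-learn stay below 2^31.
* Ridge CV evaluates the whole penalty grid from one SVD per fold.
* A constant (or single-class) outcome raises a degenerate-fit error;
  a predictor with fewer distinct values than knots raises a
  degenerate-predictor error; a fully missing column is unimputable.
* AUC with one class present is an error, not 0.5; per-replicate AUCs of
  degenerate bootstrap test sets become NaN and are excluded from means.
* Baseline-adjusted AUC change is undefined at reference AUC ≤ 0.5.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: cohorts of
500–7,000 patients, m=1–3 imputations, B=2–8 bootstraps, R=5–50 meta
replicates, and MLP widths of 8–32 where the check concerns protocol
structure rather than network capacity (width is an explicit
configuration, never a silent change; checks of the default architecture
use the full 256). The full-protocol defaults (m=10, B=20, R=200,
256-unit MLPs) remain the package defaults throughout.

## Known limitations

* The MLP relies on scikit-learn's implementation: no GPU, no per-epoch
  control beyond early stopping.
* The imputer assumes at least one fully observed column and does not
  model missing-not-at-random mechanisms.
* Between-imputation variance is propagated through predictions (the
  pipeline pools predictions, not coefficients); no Rubin pooling of
  coefficients is offered.
* The stacking registry supports more than two base-learners, but only
  the canonical ridge+MLP pair is wired in and tested.
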