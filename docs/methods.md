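# Methods

`imbcal` is a Monte Carlo pipeline for studying what class-imbalance
corrections do to the quality of logistic risk models. This note documents
the model, the procedures, the numerical choices, and what the synthetic
data can and cannot say about real cohorts.

## The question

Clinical risk models are usually developed on data where events are much
rarer than nonevents. A popular reflex is to "fix" this imbalance before
model fitting — by random undersampling of the majority class (RUS), random
oversampling of the minority class (ROS), or SMOTE's interpolated synthetic
minority cases. All three change the event fraction of the training data to
50%. A model fit on such data estimates `P(Y=1 | x, sampled design)`, not
`P(Y=1 | x)` in the population: by case–control sampling logic its logit is
shifted upward by roughly `logit(0.5) − logit(π)` where `π` is the true
event fraction. The pipeline quantifies that harm — and the repair — in
terms of discrimination (AUROC), calibration (intercept and slope),
classification (sensitivity/specificity at a threshold) and clinical
utility (Net Benefit).

## Data-generating mechanism

Predictors are `p` i.i.d. standard normal variables with zero correlation.
The outcome is Bernoulli with

    P(Y=1 | x) = expit(b0 + beta * sum_j x_j),

all `p` predictors sharing one slope (equal strength). Because the linear
predictor is Normal(`b0`, `p·beta²`), both the marginal event fraction and
the c-statistic of the true model depend only on `(b0, s)` with
`s = beta·√p`. `calibrate_generator` solves the two-target problem

* prevalence `E[expit(LP)] = π*` (targets 0.3, 0.1, 0.01), and
* c-statistic of the true linear predictor = 0.75

by nested 1-D root-finding (Brent), with the prevalence map solved for `b0`
inside the c-statistic solve for `s`. Both maps are strictly monotone, so
bracketing is robust. They are evaluated by deterministic quadrature of the
normal linear predictor on a ±10 SD grid of 4001 points; the c-statistic is
the integral of the case density against the control CDF. Calibration is
therefore deterministic — no seed enters — and the Monte Carlo checks of the
result are kept in the tests, not in the solver. An immediate consequence
used as a test invariant: `beta·√p` is the same for every `p` at fixed
targets, so the 24-predictor scenarios simply spread the same signal more
thinly.

Scenario grid (the factorial study): training size `n ∈ {2500, 5000}` ×
predictors `p ∈ {3, 6, 12, 24}` × event fraction `π ∈ {0.3, 0.1, 0.01}`,
i.e. 24 cells. Every replicate draws a fresh training set; all replicates
of a cell are evaluated on a single common test set drawn once from the
same mechanism (default 100,000 rows).

The common test set is drawn *conditional on its expected event count*
(exact conditional-Bernoulli sampling: the outcome vector is redrawn until
the total matches `round(n_test·π*)`). This is a variance-reduction device:
a plain draw of 50,000 rows at 1% prevalence carries ~0.045 SD of pure
event-count noise on the logit scale, which one single shared draw would
imprint on every calibration summary of the cell — of the same order as
the effects the uncorrected-model summaries measure. Conditioning removes
that term while leaving the conditional law of the predictors given the
outcome, and hence discrimination and within-replicate variation, intact.
Training sets are *not* conditioned: replicate-to-replicate variation in
the training event count (and the separation events it causes) is part of
the phenomenon under study.

## Imbalance corrections

All three corrections return exactly balanced classes and are deterministic
given the generator state:

* **RUS** discards a uniform random subset of majority rows; output size
  `2·n_min`. No row is fabricated.
* **ROS** resamples minority rows with replacement up to the majority
  count; output size `2·n_maj`. Extra rows are exact duplicates.
* **SMOTE** adds synthetic minority rows `x_i + u·(x_nn − x_i)` with
  `u ~ U(0,1)` and `x_nn` one of the `k = 5` nearest minority neighbours of
  `x_i` (Euclidean distance, self excluded). When the deficit is not a
  multiple of the minority count, each minority row receives
  `floor(needed/n_min)` synthetic points and a random subset receives one
  more, giving exact balance. Neighbour ties are broken by row index so the
  procedure is reproducible. `k` is clamped to `n_min − 1` with a warning
  when the minority class is tiny. For fixtures with an ordinal predictor,
  `smote_round_ordinal` rounds the interpolated column back to its integer
  range; the simulation path is all-continuous and never rounds.

## Model fitting

**SLR** — maximum-likelihood logistic regression via statsmodels GLM
(binomial family, IRLS). If the IRLS aborts (perfect separation), a bounded
Newton fallback returns the last iterate so the simulation engine can
record the event instead of crashing. Separation is flagged when any
coefficient exceeds 20 on the unit-SD scale or when every fitted training
probability is numerically 0/1; flagged fits are counted as failures in the
summaries (medians are taken over clean replicates, failure counts are
reported alongside).

**Ridge** — logistic regression with an L2 penalty on the slopes only,
never the intercept. Predictors are standardized internally (full-training
moments) so the penalty is equivariant; returned coefficients are on the
original scale. The penalty weight is chosen from 30 log-spaced values in
`[1e-4, 1e2]` by 10-fold cross-validation stratified on the outcome
(without stratification, folds at a 1% event fraction frequently contain no
events), minimizing the summed out-of-fold binomial deviance; ties resolve
to the larger penalty. The final model is refit on the full data at the
chosen weight.

Numerics: the solver is a penalized Newton (IRLS) iteration. The full-data
path is computed first, warm-starting each penalty from the next-larger
one. Fold fits warm-start from the full-data solution at the same penalty
plus the fold-offset carried along the path (a predictor–corrector start),
which leaves them one or two Newton steps from their optimum; they run in a
compiled (numba) kernel with an infinity-norm trust-region cap of 2 and a
step tolerance of 5e-3. The deviance error from that loose tolerance is
O(n·w·tol²) ≈ 1e-4 — far below the between-penalty deviance differences the
CV compares — while the final refit is solved to 1e-10. Standardizing on
the full data rather than per fold perturbs fold moments by O(n^-1/2) and
lets every fold share one design matrix; it is the package's deliberate
trade of a negligible statistical nicety for a large constant factor.

**Splines** — restricted cubic splines in Harrell's parameterization:
piecewise cubic, constrained to linearity beyond the boundary knots, knots
at the 0.10/0.50/0.90 quantiles for 3 knots, giving `n_knots − 1` design
columns per variable (linear term + one nonlinear term for 3 knots).
Columns with too few distinct values fall back to a linear term with a
warning. The simulation path uses the identity basis (the true model is
linear); splines are exercised on the case-study fixture.

**Recalibration** — logistic recalibration-in-the-large: the model's logit
predictions enter as an offset with coefficient fixed at 1 and only the
intercept is refit, on the *original, imbalanced* training data. By the
score equation of the intercept-only MLE the mean recalibrated probability
equals the observed event fraction, which is exactly the repair the
corrections need; recalibrating on the balanced data would be a no-op.
Solved by bracketed root-finding of the monotone score equation.

All probabilities are clipped to `[1e-10, 1 − 1e-10]` before any logit, so
the offset regressions downstream always see finite values.

## Performance metrics

* **AUROC**: rank-sum (Wilcoxon/Mann–Whitney) form with midranks, i.e. the
  exact pairwise concordance probability with ties counted 1/2 — not a
  trapezoidal ROC integral (they agree, but the concordance definition is
  the estimand).
* **Calibration intercept**: intercept `a` of `logit P(Y=1) = a + LP` with
  the model's logit `LP` as an offset. Negative `a` ⇒ overestimated risks.
  Fit by Newton with an analytic warm start (`logit(ȳ) − mean(LP)`); a
  bracketed root-finder is the fallback.
* **Calibration slope**: `b` in `logit P(Y=1) = a' + b·LP`; `b < 1` ⇒
  predictions too extreme. Undefined (NaN) for constant predictions.
* **Flexible calibration curve**: lowess (span 0.75, zero robustness
  iterations) of the outcome against `LP`, read off on a 100-point evenly
  spaced grid of predicted probabilities over the observed range. The
  smooth is fit on the logit axis but on the probability outcome scale;
  needs ≥ 50 observations.
* **Classification** at threshold `t`: high risk iff `p̂ ≥ t` (a prediction
  exactly at the threshold is high risk). Accuracy, sensitivity,
  specificity from the confusion counts.
* **Net Benefit**: `(TP − (t/(1−t))·FP)/N`, with treat-all
  (`π − (t/(1−t))(1−π)`) and treat-none (0) reference strategies;
  `decision_curve` tabulates all three over `t ∈ {0.05, …, 0.50}` by
  default.

## Simulation engine and protocol

Per replicate: draw a training set; build the four variants (uncorrected,
RUS, ROS, SMOTE); fit SLR and Ridge on each (8 models); recalibrate the 6
corrected models' intercepts on the original training data — 14 models,
each evaluated on the scenario's common test set. Classification uses the
0.5 threshold everywhere, plus a threshold equal to the true event fraction
for the uncorrected models (threshold-shifting is the cheap alternative the
study compares against). Fit failures and separation are recorded per cell;
cell summaries report medians and quartiles over clean replicates together
with the failure counts (no imputation).

Seeding: every draw derives from a `SeedSequence` keyed on
`(base_seed, n_train, p, round(ef·1e5), stream)` where `stream` is the
replicate index or a reserved tag for the cell's test set. Results are
therefore bit-reproducible and independent of execution order; grid-level
parallelism (joblib) cannot change them. `run_grid` writes per-scenario
summary files and resumes past completed cells.

Problem sizes: the shipped presets run 200 replicates per cell (the full
study used 2,000) and a 50,000-row test set in the reduced preset
(`run_reduced_study`: grid restricted to `p ∈ {3, 24}`, full 14-model
protocol on the `n=5000, p=3` cells, uncorrected-only elsewhere). These
sizes keep a desk-scale single-CPU run in the tens of minutes while leaving
the medians stable to well within the effects being measured (the
correction-induced intercept shifts are 0.8–4.6 logits; median Monte Carlo
error at 200 replicates is on the order of 0.01–0.03).

## The case-study fixture

`generate_case_study_fixture` emulates the *structure* of a premenopausal
ovarian-tumour diagnosis cohort: age in years (truncated normal on
[18, 59]), maximum lesion diameter in mm (log-normal), papillation count
(ordinal 0–4, three-quarters zero), event fraction 0.20, and a deliberately
nonlinear (quadratic in log) diameter effect so the spline machinery has
something to find. All coefficients are fixed synthetic constants; the
intercept was solved once so the expected event fraction is 0.20. It is a
stand-in: no real cohort quantity should be read off it, and no acceptance
quantity depends on it.

## What the synthetic data does not show

The generator is the cleanest possible world: independent Gaussian
predictors of equal strength, a correctly specified linear logit, no
missingness, no measurement error, no covariate shift. Passing results
demonstrate the *mechanisms* — the case–control offset induced by
balancing, SMOTE/ROS overfitting pressure on the slope, the degeneracy of
the 0.5 threshold at 1% prevalence — not the magnitudes to expect on any
particular clinical dataset, where correlated predictors, nonlinearity and
model misspecification interact with these effects.

## Known limitations

* Ridge CV deviance is summed over folds of a single stratified split; no
  repeated CV.
* The lowess calibration curve extrapolates poorly into regions with
  almost no observations; judge it within the bulk of the predicted-risk
  distribution.
* Separation handling is flag-and-record; no Firth-type remedy is
  provided.
* Event fractions above 0.5, correlated or non-normal predictors, and
  unequal true coefficients are out of scope of the generator.
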