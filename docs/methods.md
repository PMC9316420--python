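# Methods

This note records the statistical procedures `dtsurv` implements, the
conventions and defaults it fixes where several choices were defensible,
and what its synthetic-data tests do and do not establish about behaviour
on real data.

## Data model and assumptions

The observed data are subject-level triples `(T̃_i, δ_i, X_i)`:
follow-up time `T̃_i = min(T_i, C_i)`, event indicator
`δ_i = I(T_i ≤ C_i)`, and a fixed baseline covariate vector. Throughout,
censoring is assumed noninformative given covariates, covariates are
time-fixed, and only right censoring is modelled. Missing covariates are
rejected at load (complete-case analysis); left truncation,
interval-censored observation and competing risks are out of scope.
Subjects with an observed event at exactly `t = 0` are rejected, because
no left-open interval `(t_{j-1}, t_j]` can contain them.

## Discretization

Follow-up is cut at a horizon `w` (administrative censoring: any subject
still under observation past `w` is treated as event-free at `w`) and the
range `(0, w]` is split into `J` intervals. Interior cut points are the
`k/J` empirical quantiles of the observed event times within the horizon,
computed as order statistics (inverted-CDF definition) rather than by
interpolation, so every interior cut coincides with an observed event
time; with `J = 5` and event times `1..5` on horizon 5 this yields exactly
the unit grid. Tied event times can make quantiles coincide; duplicates
are collapsed with a warning and the realized interval count is reported
on the grid object, rather than failing, because heavily tied data would
otherwise make large `J` unusable.

The interval convention is left-open/right-closed everywhere: a time equal
to a cut point belongs to the interval ending there, and a subject
censored exactly at a cut point has survived that interval in full under
every censoring rule.

## Person-period expansion

An event subject whose event falls in interval `j_i` contributes rows
`1..j_i` with the event-history indicator `d` zero except in the last
row. For censored subjects three rules are implemented, differing only in
how the final, partially observed interval is counted:

* `observed_any` — every interval in which the subject was observed at
  the start (at risk);
* `half_interval` — an interval counts only if at least half of it was
  survived;
* `full_interval` — only fully survived intervals count (equivalent to
  moving the censoring time back to the previous cut point).

`observed_any` can bias hazards downward when censoring is heavy and
intervals are long (the subject is credited with surviving time they were
not observed for); the other two rules trade a little data for less bias.
Event subjects are expanded identically under all three rules; the rules
as defined concern censored subjects only, and we deliberately leave event
rows untouched rather than inventing a reassignment for events in the
first half of an interval. A subject whose rule yields zero rows is
dropped from the table, counted, and reported through a warning — never
silently discarded.

## Hazard estimation

On the person-period table the discrete-time survival likelihood equals a
binomial likelihood over rows, so two estimation routes are provided
behind one interface:

* **Link models** `g(λ_j|x) = α_j + β x` with
  `g ∈ {logit, cloglog, probit, loglog, log}`, fitted by IRLS through a
  binomial GLM with one dummy per interval and no global intercept, so
  `α_j` is each interval's baseline coefficient directly. An interval with
  no rows leaves its `α_j` unidentified and raises an error suggesting a
  smaller `J`. Non-convergence, a non-finite standard error, or a
  coefficient beyond ±30 on the link scale (far outside any plausible
  hazard) is reported as separation/divergence rather than returned.
  Covariates are left on their natural scale so coefficients stay
  interpretable.
* **Classifier models** `λ_j(x) = f(x, A_j)` for any object exposing
  `fit(features, labels)` and `predict_probability(features)`. Covariates
  are standardized by mean/sd computed over *unique subjects* (row-level
  moments would weight subjects by their follow-up length), the interval
  enters one-hot by default or as a single ordinal column (useful for
  tree learners), and no sample weights are passed — each person-period
  row counts once, matching the binomial likelihood. Seeds thread through
  the classifier adapter into `random_state`, so a fixed seed reproduces
  identical hazards.

Survival is composed as `S(t|x) = ∏_{t_j ≤ t} (1 − λ_j(x))`, a
right-continuous step function; evaluation beyond the horizon is refused
rather than extrapolated. Two clipping constants guard the composition:
classifier outputs are clipped to `(1e−6, 1 − 1e−6)` before the product
(one overconfident prediction must not collapse `S` to exactly 0), and
hazards entering log-likelihood evaluation are clipped at `1e−12` with a
warning counting the clipped rows.

## Evaluation

All metrics consume only a matrix of predicted event probabilities
`p_i(t) = 1 − S_i(t)`, so discrete-time, continuous-time and external
predictions are scored identically. Censoring is handled by inverse
probability of censoring weighting with the Kaplan–Meier estimate `Ĝ` of
the censoring survival (lifelines product-limit backend, event roles
flipped):

* subjects with `T̃ > t` weigh `1/Ĝ(t)`;
* subjects with an observed event by `t` weigh `1/Ĝ(T̃−)` — the left
  limit, the standard convention that keeps a subject's own censoring
  mass out of its weight;
* subjects censored by `t` weigh 0.

`Ĝ` is estimated on the evaluation split by default; a training-split
estimate can be supplied. A weight that would require dividing by
`Ĝ = 0` raises an error naming the offending time instead of silently
extrapolating beyond the censoring support.

The time-dependent AUC is the cumulative/dynamic weighted double sum
(cases: event by `t`; controls: event-free at `t`); tied predictions
contribute 0, exactly as the strict inequality in the estimand, with an
optional half-credit setting. Zero weighted cases or controls raises an
undefined-metric error, never a silent 0.5. The Brier score is
`(1/n) Σ W_i(t) (D_i(t) − p_i(t))²`; `R²(t) = 1 − BS(t)/BS₀(t)` scales it
against a null model that assigns every subject the marginal Kaplan–Meier
event probability of the evaluation data, so the null predictor's `R²` is
exactly 0 there. The integrated Brier score uses the weight function
`W(t) = t/t*`, i.e. `(1/t*)∫₀^{t*} BS(s) ds`, by the trapezoidal rule
with constant extension from the first and last evaluated times to the
ends of the range. Both implementations agree with scikit-survival's
independent estimators to numerical precision on tie-free data (test
suite cross-checks).

## Tuning and validation

Splits are subject-level and stratified by event status by default (small
data must not produce event-free folds): within each stratum subjects are
shuffled and given fractional ranks, and sorting by rank interleaves the
strata so exact global split sizes are kept. Holdout defaults to
60/20/20 train/validation/test; K-fold deals the stratified order
round-robin.

The search space for a discrete-time method is the Cartesian product of
its classifier hyperparameters and the number of intervals (default
candidates 2–25; 25 is the ceiling beyond which the person-period table
grows with little predictive return). Grid search enumerates the product;
random search samples a fixed budget from it. A model-based (Bayesian)
strategy is declared but has no backend and raises. Each trial fits on
training data only, scores the Brier objective (at one time, or the IBS
over several) on validation data, and is logged; failed trials are
recorded and skipped, and only if all fail is the aggregate raised.

After tuning, holdout models are refitted on the training split only by
default — refitting on train+validation is available but changes what the
recorded validation objective refers to, so the honest default is off.
Under K-fold the fold's training portion is itself split 75/25 for
tuning, and the selected configuration is refitted on the full fold
training portion before scoring on the fold; reported metrics are the
arithmetic mean across folds, with per-fold values retained in the report
for audit. All randomness descends from one root seed via
`SeedSequence`, expanded per method and per fold; the benchmark report's
canonical JSON excludes wall-clock timing (stored on the object,
serialized only on request), so a re-run with the same configuration is
byte-identical.

## Synthetic-data generator

The generator emulates a mid-sized clinical prognosis study: default
`n = 1000` subjects, five covariates (three standard normal, two balanced
binary) with moderate log-hazard effects `(0.5, −0.5, 0.25, 0.5, −0.25)`,
a Weibull baseline with gently increasing hazard (shape 1.5, scale 8),
and 50% independent censoring — the middle of the 42–86% range typical of
the public survival datasets this kind of model is benchmarked on.
Event times come from proportional-hazards families with closed-form
survival (exponential, Weibull, piecewise-constant hazard) by inversion
sampling, or natively in discrete time from specified per-interval
hazards with a logistic covariate shift. Censoring times are drawn
independently of event times from a uniform, exponential or fixed
(administrative) distribution whose parameter is calibrated by
root-finding so the expected censored fraction — analytic given the
realized event times — hits the target; unattainable targets raise. A
documented threshold scenario (a step effect invisible to a linear model)
exercises the claim that flexible classifiers beat the linear logit
hazard model when the true effect is nonlinear.

Every generated dataset retains its uncensored event times and exposes
the true `S(t|x)` and the implied per-interval hazards
`λ_j(x) = [S(t_{j-1}|x) − S(t_j|x)]/S(t_{j-1}|x)` for any grid, so the
test suite can check estimates against exact estimands: the grouped-PH
(cloglog) model recovers a true log hazard ratio of 0.7 with mean
absolute error below 0.1 at `n = 2000`, `J = 25` over ten replicates, and
the IPCW Brier score on 30%-censored data (`n = 5000`) matches the
uncensored oracle Brier on the same realizations within 0.01.

What the generator does *not* emulate: tied or coarsened recording times,
informative or covariate-dependent censoring, time-varying covariates,
missing data, and the correlated covariate structure of real clinical
registries. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated sampling assumptions, not
predictive performance on any particular clinical dataset.

## Problem sizes

The test suite runs at deliberately desk-sized scales — hundreds to a few
thousand subjects, grids up to 25 intervals, benchmark configurations
with two methods and five folds on `n = 500` — chosen so the full suite
completes in well under a minute while the Monte-Carlo tolerances above
remain comfortably resolvable.

## Known limitations

* The parametric links share one `β` across intervals (proportionality on
  the link scale); non-proportional effects require the classifier route.
* Classifier features expose the interval only as a categorical label;
  numeric interval endpoints as features are a possible extension, not
  implemented.
* Metrics come without confidence intervals, and only the
  cumulative/dynamic definition of the time-dependent AUC is provided.
* Model persistence uses Python pickling; archives are not portable
  across major library versions.
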