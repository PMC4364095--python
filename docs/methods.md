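# Methods

## The problem

Prospective cardiovascular cohorts usually analyze *time to first event*: a
subject who survives a myocardial infarction and later has two strokes and a
revascularization contributes exactly one observation. That convention
understates the total cardiovascular burden attributable to a risk factor.
`weibmix` implements and compares four parametric survival models of the
same event history, all built on the Weibull hazard, that progressively add
the ignored structure: recurrences of the same event type, multiple distinct
event types, and both at once.

## The four models

Throughout, time `y` is years from baseline, covariates `x` are
baseline-fixed, and the Weibull density is parameterized as

    f(y) = lam * rho * y^(rho-1) * exp(-lam * y^rho),
    lam = exp(beta0 + beta' x + offset),

so covariate effects are proportional-hazards log-hazard-ratios and `rho`
controls hazard shape (rho < 1 decreasing, rho = 1 exponential, rho > 1
increasing).

* **m1 — time-to-first-event.** One row per subject: the earliest event of
  any type, or administrative censoring. No random effects.
* **m2 — recurrent events.** All event occurrences pooled over types, with a
  shared subject-level normal offset a_i ~ N(0, sigma^2) in the log scale
  (a log-normal frailty) capturing within-subject correlation.
* **m3 — multivariate event types.** First occurrence of each of the K
  event types, with a type-specific shape rho_k (each event type gets its
  own baseline hazard), a shared intercept beta0, and a subject-level offset
  b_i ~ N(0, tau^2) shared across types.
* **m4 — joint recurrent + multivariate.** All occurrences of all types,
  type-specific shapes, and two independent normal offsets: a
  subject-by-type effect c_ik ~ N(0, chi^2) and a subject effect
  d_i ~ N(0, delta^2).

A single coefficient vector `beta` is shared across event types in m3/m4:
the target of inference is overall burden, not type-specific effects.
(Per-type intercepts are deliberately not freed; the type-specific shape
already gives each type its own baseline hazard level at any fixed time.)

## Likelihood for recurrent rows

Model frames carry an `entry` column: the time the subject became at risk
for that row on the total-time (calendar) clock — zero for first rows, the
previous same-stream event time for later occurrences. A row with entry e,
exit t and event indicator s contributes

    s * log h(t) + [log S(t) - log S(e)],

the log hazard at the event plus the survival increment over the at-risk
interval. For first-event rows this is exactly `s*log f + (1-s)*log S`; for
recurrent rows it is the left-truncated contribution, and summed over a
stream it equals the likelihood of the total-time counting process with
Weibull intensity — precisely the process the simulator generates. Treating
each recurrent time as an unconditional Weibull draw instead would be
internally inconsistent (the likelihood would not match any generative
process producing ordered times) and demonstrably biases the rate estimates;
the truncation form keeps estimator and generator aligned, which the
parameter-recovery suite verifies end to end. A `gap` timescale is available
as a configuration option: the clock restarts after each event and rows
become independent renewal gaps with entry 0.

Events recorded at exactly t = 0 are undefined under rho != 1 (log t);
frame construction shifts them to half the smallest positive time with a
logged warning. Ties across different event types are retained; ties within
a type are a validation error.

## Marginal likelihood and estimation

Random effects are integrated out by non-adaptive Gauss-Hermite quadrature
with standardized nodes (offset = sd * sqrt(2) * z_q, weight w_q / sqrt(pi)),
default 15 nodes per dimension. For m4 the (K+1)-dimensional integral
factorizes — the c_ik are independent across types and of d_i — into an
outer rule over d and, inside each outer node, K one-dimensional rules over
c, so per-subject cost is O(Q^2 * rows) rather than O(Q^(K+1)).

Because covariates are baseline-fixed, each (subject, type) stream's
conditional log-likelihood collapses to `A + S*u - G*exp(u)` in the scalar
offset u, where A, S, G are per-stream aggregates (event log-hazard terms,
event count, cumulative baseline hazard mass). One likelihood evaluation is
therefore a single pass over the rows plus stream-by-node arithmetic, and
the *score is available in closed form* through the same softmax weights the
quadrature produces. Fits use BFGS on the analytic gradient; shapes and
random-effect SDs are estimated on the log scale (unconstrained optimization
with positivity by construction) and reported on the natural scale.

* Convergence: optimizer success, with an L-BFGS-B polishing pass if the
  first line search stalls; non-convergence is reported on the results
  object, never raised.
* Standard errors: observed information — a central-difference Hessian of
  the analytic score at the optimum (step 1e-5 relative). The covariance is
  reported on the internal (log) scale; natural-scale SEs and CIs use the
  delta method / exponentiated endpoints. A singular information matrix
  flags the covariance unusable rather than failing the fit.
* Initialization "auto": a pooled (zero-frailty) fit of the same frame seeds
  beta0, beta and the shapes; random-effect SDs start at 0.3. Warm starts
  keep the mixed fits in the attraction basin of the interior optimum.
* Quadrature accuracy: 15 vs 31 nodes agree to < 1e-5 on the test fixtures;
  the joint model is fitted with 9 nodes per dimension in the large-cohort
  scripts (81 joint nodes), which the node-convergence checks support for
  SDs up to about 1.

## Marginalized (population-averaged) hazard ratios

exp(beta) from a mixed model is conditional on the frailty, so it is not
comparable with the m1 estimate. The package therefore integrates the fitted
random effects out of the survival function:

    S_m(t | x) = E_u exp(-exp(beta0 + beta'x + u) t^rho),  u ~ N(0, v),

with v = sigma^2, tau^2, or chi^2 + delta^2 (independent effects sum).
Marginal hazards under normal frailty are *not* proportional, so a
single-number summary requires a convention. The reported marginal HR is the
exponentiated average over a time grid (default: 20 equally spaced points on
(0, median follow-up]) of

    log Lambda_m(t | x1) - log Lambda_m(t | x0),   Lambda_m = -log S_m.

Properties: with v = 0 it equals exp(beta) exactly on every grid; as t -> 0
it tends to exp(beta); for beta > 0 it lies strictly between 1 and
exp(beta) and is attenuated monotonically as v grows. A pointwise-at-one-time
variant is available by passing a single-point grid. For type-specific-shape
models the representative shape is the geometric mean of the rho_k (the
grid-averaged log-CH ratio is insensitive to this choice; a specific event
type can be requested instead).

Confidence intervals use the delta method: a central-difference gradient of
the grid-averaged log marginal HR with respect to the internal parameter
vector, propagated through the fit covariance. Reference covariates are held
at sample means (continuous) or modes (indicators), configurable.

## The synthetic cohort

Real data of this kind (a large elderly CVD cohort with ~5,800 subjects,
adjudicated events of ~10 types over 8-13 years of follow-up) sit behind a
controlled-access repository, so the package ships a generator that emulates
the published structure and makes every pipeline stage testable offline.

Per subject: baseline covariates from the published prevalence/mean table
(42.6% male, 16.5% diabetes, 12.1% current smoking, SBP 136.6 (21.9), ...);
follow-up ~ Uniform(8, 13) years; d_i ~ N(0, delta^2) and c_ik ~ N(0, chi^2)
drawn independently; each (subject, type) stream is a total-time counting
process with Weibull intensity, successive times by conditional inversion
T' = (T_prev^rho - log U / lam)^(1/rho), capped at 44 events per stream
(the published maximum per-subject count). One root seed spawns per-subject
child RNG streams, so cohorts are byte-identical across runs and independent
of generation order.

Default truth (`chs_like_config`): K = 10 types with shapes 0.9-1.3,
chi = 0.4, delta = 0.9, beta0 = -5.50, and plausible conditional
log-hazard-ratios for the classic risk factors (current smoking 0.66,
diabetes 0.61, prior CVD 0.55, male 0.41, ...). beta0 and the frailty SDs
were calibrated once, by simulation, to two published facts about the
emulated cohort: the 0 / 1 / 2+ event split of roughly 31% / 27% / 41%
(achieved: ~32 / 25 / 43) and the mean event count of ~2.2 per subject. A
subject-level SD near 1.1 reproduces the 2+ fraction but drains the
single-event class below the published bracket; 0.9 with chi = 0.4 satisfies
both facts simultaneously. These constants are fixture choices that emulate
the cohort's structure, not estimates of it.

What the generator does *not* emulate: event adjudication noise, missed or
misclassified endpoints, death as a competing risk (death acts purely as
administrative censoring), covariate correlation (covariates are drawn
independently), and dropout other than administrative censoring. Passing
recovery tests therefore demonstrate correctness of the estimators under
the models' own assumptions — not robustness to the messiness of real
registry data.

## Verification strategy

* Closed-form and numeric-integration oracles for the Weibull primitives
  (density integrates to 1; moments match quadrature; hazard monotone in
  the shape regimes).
* The conditional likelihood is checked row-by-row against an independent
  summation built only from the public log-hazard/log-survival functions.
* The Gauss-Hermite marginal likelihood is checked against dense trapezoid
  integration over +/- 8 SD grids (nested grids for the joint model) to
  1e-6 on small fixtures, and for exact degeneration at zero variance.
* The analytic score is checked against central finite differences for all
  four models.
* The m1 fit is cross-checked against an independent Weibull AFT
  implementation (lifelines), translating its accelerated-failure-time
  coefficients to proportional-hazards scale via beta_ph = -rho * beta_aft.
* Simulation recovery: for m1, m2, m4 at n = 1,000 (K = 3 for the joint
  model), 20 replicates each — mean bias of the covariate effect within
  0.1 and 95% Wald coverage of at least 17/20, including the frailty SD.
* Direction of the headline comparison: on joint-model data the joint
  model's marginalized HR exceeds the first-event HR on average across
  replicates.

Problem sizes in the test suite (n = 250-2,000, K = 1-3, 9-31 quadrature
nodes) were chosen so the full suite completes in a few minutes on one core;
the acceptance script runs the cohort-scale analysis (n = 5,795, K = 10,
joint model at 9 nodes per dimension).

## Known limitations

* Non-adaptive quadrature loses accuracy for random-effect SDs well above
  ~2 at the default node counts; adaptive (mode-centered) quadrature is a
  natural extension and is not implemented.
* Death is not a competing risk; estimates are cause-specific in that sense,
  matching the censoring convention of the emulated study.
* No type-specific covariate effects, by design (shared beta).
* The marginal-HR convention (grid-averaged cumulative-hazard ratio) is one
  of several defensible single-number summaries of a non-proportional
  marginal contrast; pointwise values at chosen times can differ.
* Wald/observed-information inference; no profile likelihood or robust
  (sandwich) variance for misspecification.
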