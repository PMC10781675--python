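# Methods

## The model

We model each patient's first year after cancer diagnosis as a progressive
illness–death process with three states — alive untreated (1), alive treated
(2), dead (3) — and three transitions h₁: 1→2, h₂: 1→3, h₃: 2→3. There is no
recovery transition and death is absorbing. All hazards run on the shared
time-since-diagnosis clock and the process is Markov (clock-forward): the
hazard of the next transition depends on the current state and time since
diagnosis, not on how long the patient has been in the state. Follow-up is
administratively censored at 365.24 days.

Each transition hazard is a flexible parametric (Royston–Parmar) model,
`log H(t|x) = s(log t; γ) + x'β`, where `s` is a restricted cubic spline
(linear tails beyond its boundary knots) and covariates act proportionally on
the hazard. With no interior knots (df = 1) the model is exactly a Weibull
regression, which anchors several oracle tests. The likelihood for a row with
entry time t₀, exit time t and event flag d is

    d·[log s'(log t) − log t + η(t)] − exp(η(t)) + 1{t₀ > 0}·exp(η(t₀)),

where η is the log cumulative hazard. The exp(η(t₀)) term conditions on
survival to the entry time; it is what makes the treatment→death fit immune to
immortal-time bias (treated patients enter that risk set only at their
treatment time). Gradient and Hessian are analytic; optimisation is Newton
with step halving and a ridge fallback, initialised by regressing the log
Nelson–Aalen cumulative hazard (left-truncation-aware) on the spline basis.
A fit converges when the scaled gradient norm falls below 1e-5 (typical
optima reach 1e-10); the covariance is the inverse observed information.
Constant (zero-variance) dummy columns are dropped before fitting, which
treats empty covariate levels as the reference.

Prediction combines the three fits into occupancy probabilities

    P₁₁(t) = exp(−[H₁+H₂](t|x)),
    P₁₂(t) = ∫₀ᵗ P₁₁(u) h₁(u|x) exp(−[H₃(t|x) − H₃(u|x)]) du,
    P₁₃ = 1 − P₁₁ − P₁₂,

using the direct integral representation (the progressive structure makes a
general ODE solver unnecessary; an ODE cross-check of the Kolmogorov forward
equations lives in the test suite). Restricted lengths of stay are
L_k(τ) = ∫₀^τ P₁k, with L₃ = τ − L₁ − L₂ read as days of life lost.

## Covariates and reference profile

Adjustment covariates: income-deprivation quintile (1 = least deprived,
reference), age as a restricted cubic spline with four knots at the
5/35/65/95 percentiles of the analysis cohort's ages (recomputed per
stratum), sex (men reference), ethnicity (White reference), heart failure,
myocardial infarction, diabetes with complications, chronic pulmonary
disease, and route to diagnosis (standard GP referral reference; emergency,
inpatient elective, other outpatient, screening, two-week-wait). Predictions
and contrasts are reported at the reference profile — White, male, 75 years,
no comorbidity, GP referral — varying only the deprivation quintile, with
arbitrary profile pairs supported.

## Numerical choices

- **Baseline knots.** Interior knots at equally spaced centiles of the
  uncensored log event times, boundary knots at their min/max — the standard
  convention for this model family. The df grid for selection defaults to
  1–3 in the drivers (1–6 supported); with `criterion="both"` the BIC winner
  is taken (parsimony) and AIC disagreement is recorded in the selection
  table. Fits whose spline slope goes non-positive anywhere on the observed
  event-time range (negative hazard) are excluded from selection.
- **Quadrature.** Fitted hazards behave like t^(a−1) near the origin with a
  possibly below 1, so the occupancy integrand has an integrable endpoint
  singularity. The first panel (from 0 to the first evaluation time) is
  integrated with a ~100-node tanh-sinh rule, which handles the singularity
  at near machine precision; subsequent inter-grid panels use 32-node
  Gauss–Legendre (64 nodes changes P₁₂ by < 2e-9). The accumulation keeps a
  running exp(−H₃) offset so every exponent is non-positive, which keeps
  extreme parameter draws finite.
- **Reporting grid.** Monthly, i.e. multiples of 365.24/12 days, so "6
  months" and "1 year" are exact grid points; a finer (e.g. daily) grid is a
  parameter. Horizon 365.24 days; no extrapolation beyond it.
- **Uncertainty.** Multivariate-normal simulation of (γ, β) per transition
  (independent across transitions, which are fitted separately), default
  1,000 draws, pointwise 2.5/97.5 percentile bands. Draws depend only on the
  fits and the seed — not the profile — so two profiles computed with the
  same seed are paired draw-by-draw and contrast intervals come from the
  paired differences. Negative eigenvalues of near-singular covariances are
  clipped to zero before drawing; the log cumulative hazard of a draw is
  capped at 80 (certain death) to keep pathological draws finite. Bands are
  clipped to [0, 1]. A delta-method alternative was considered and not
  implemented: percentile simulation propagates through all the nonlinear
  functionals (occupancy, lengths of stay, differences) with one mechanism.
- **Same-day jitter.** Transition times equal to the previous state's entry
  time get an independent uniform draw on [0.1, 0.9] of a day added (uniform
  is the minimal assumption; bounds configurable). When jitter breaks the
  t_treat < t_death ordering the draws are repeated — jointly for
  double-tied patients — rather than clipped, preserving the stated support.
  Jitter is seeded, idempotent on tie-free data, and never changes event
  indicators. Degenerate inputs (a death recorded at a fraction of a day
  below 0.1 with a same-day treatment) are rejected with an error rather
  than silently reordered.
- **Filters.** Applied in a fixed order with an order-dependent tally: age
  outside [18, 99], death-certificate-only flag, missing diagnosis month,
  improper dates (death before diagnosis, treatment after death),
  complete-case drop on deprivation/ethnicity/route. Missing stage is never
  dropped or imputed — those patients form their own analysis stratum.
- **Stratification.** Site × stage strata fitted independently; strata with
  fewer than 10 events on any transition (configurable) are skipped with a
  logged reason. Per-stratum jitter and draw seeds are spawned
  deterministically from the master seed, so re-running a configuration
  reproduces every output byte for byte.

## The synthetic-registry generator

The generator emulates the patient-level table a cancer registry would
provide after linkage and derivation: already-derived covariates and event
times, one row per patient. Covariates are drawn from stated marginals; the
`colon_stage4_like` preset copies the advanced-colon-cancer column of
published registry descriptives (women 46.3%, White 94.8%, emergency route
28.2%, quintile shares 21–17%, comorbidity prevalences 0.8–12.6%), with age
from a normal(72, 12) truncated to [18, 99].

Event histories follow the same illness–death process the estimator assumes:
latent times to treatment and pre-treatment death by inverse transform from
the covariate-specific cumulative hazards (closed-form for constant/Weibull
baselines; safeguarded Newton to 1e-10 days for spline baselines), first
event wins; post-treatment death is drawn from H₃ conditional on survival to
the treatment time on the shared clock (a clock-reset option exists, off by
default). Baseline rates in the preset were fixed once so that, at constant
hazards, roughly a third of patients die before any treatment within the
year — the level seen in advanced colon cancer — with most survivors treated
within a few months; deprivation effects default to most-vs-least HRs 0.8 /
1.3 / 1.2 on h₁ / h₂ / h₃ with a log-linear gradient across quintiles. All
preset values are illustrative calibrations, not reproductions of any
registry estimate.

Same-day ties are created by re-recording a fraction (default 5%) of treated
patients' treatment times as day 0, mimicking date-rounding in registries.
This is deliberate measurement error: recorded times for those patients
differ from the latent ones, which attenuates fitted log hazard ratios by
roughly half a percent of a standard error at the default fraction —
negligible for every check in the suite, and documented here because it is a
feature of the recorded-data process, not an estimator defect.

What the generator does **not** emulate: diagnostic pathways, linkage error,
informative missingness (only stage can be missing, completely at random via
its marginal), non-proportional or history-dependent hazards, and calendar
effects beyond a uniform diagnosis year. Passing tests therefore show that
the estimation machinery is correct under a correctly specified Markov
proportional-hazards process of realistic size and shape — not that the
model is correct for any particular real registry.

## Validation design

Every numerical claim is checked against an independent oracle: the analytic
constant-hazard illness–death solution (exact), an adaptive ODE solve of the
forward equations (1e-5), a 500,000-path microsimulation from the fitted
hazards (3 binomial SE), Kaplan–Meier and Weibull maximum likelihood from an
independent library, and the generator's own truth curves for parameter and
contrast recovery. Interval calibration (Wald CIs for log-HRs, percentile
bands for P₁₂) is measured over 200 replicates at n = 5,000; selection
consistency over 50 replicates at n = 10,000; null calibration of the
end-to-end deprivation contrasts over 20 replicates at n = 4,000 with 300
draws. These replicate counts and cohort sizes are the package's chosen
desk-scale study conditions; all are parameters.

## Known limitations

- Proportional hazards only: no time-dependent effects, frailty or cure
  fraction.
- Clock-forward prediction only; the clock-reset (semi-Markov) option exists
  in the generator but the estimator always uses time since diagnosis.
- Percentile intervals need enough draws (hundreds) to be stable in the far
  tails; the defaults are adequate for 95% bands.
- Transition fits are treated as independent when simulating parameters; any
  between-transition correlation induced by shared patients is ignored, as
  is conventional when transitions are fitted separately.
- No multiple imputation: incomplete covariates are dropped (complete-case),
  and missing stage is a stratum, never imputed.
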