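# Methods

## Survival model

The estimator is the classical piecewise-exponential ("person-time
Poisson") extension of Poisson regression. Follow-up is divided into
1-month intervals (1/12 year exactly; follow-up is recorded in years, so no
calendar anchoring is attempted). For a fracture outcome, a subject's time
at risk is

    T = min(first qualifying fracture, loss to follow-up, death, end of follow-up),

expanded into `ceil(12T)` intervals; the final interval keeps its true
length as likelihood exposure rather than being rounded to a full month, so
Σ Δt reproduces T to float precision. One fracture per person is counted —
the first qualifying one per outcome definition — and an event exactly on
an interval boundary belongs to the earlier interval (half-open intervals).
A fracture coincident with death counts as a fracture; this is the
conservative reading when time to first fracture is the estimand.

Each interval contributes `y·log(λΔt) − λΔt` with
`λ = exp(β₀ + β₁t + β₂·age + β₃x + Σβₖzₖ)`; time and age enter linearly
(no splines). The log-likelihood is concave, maximized by Newton–Raphson
with step-halving; initialization puts the intercept at the crude log event
rate and all slopes at zero. Convergence requires a relative log-likelihood
change below 1e−10 (or a vanishing score), with a 100-iteration cap;
non-convergence is flagged, never silent. The covariance is the inverse
observed information at the optimum; intervals are Wald (±1.96·SE) and all
p-values two-sided. A non-intercept coefficient drifting beyond ±20 is
diagnosed as separation (no events in a covariate stratum) and raised as an
error — the intercept is exempt because raw-scale current age legitimately
pushes it far negative.

Exposures are standardized within cohort by the sample SD (n−1 denominator)
at the subject level before splitting, so the gradient of risk (GR) is the
hazard ratio per within-cohort SD. Cohort-specific SDs are the default;
pooled-SD standardization would be a one-line change but is not the
estimand used here. Adjusters enter on their raw scales — T-score is
already in SD units, FRAX probabilities enter untransformed on the percent
scale (a documented assumption; a log transform is defensible but was not
chosen), BMI per kg/m², prior falls as a 0/1 indicator — except the "other
pQCT measure" adjuster, which is standardized identically to the exposure.

### Competing mortality

Headline GRs are cause-specific: death censors the fracture process. The
duplicated-record construction is also provided: the subject's person-months
are stacked twice, a fracture stratum and a death stratum (time at risk to
`min(death, loss, follow-up)`, event = observed death), each with its own
coefficient block. Because the blocks share no parameters, the joint fit on
duplicated data coincides with the separate cause-specific fits — this is
asserted in the tests — so the duplication is exposed as a sensitivity/
extension layout (e.g. for later shared-parameter variants) rather than a
different headline estimator.

### Complete-case handling

Each analysis cell drops subjects missing any required covariate *before*
standardization and splitting. FRAX-adjusted rows therefore run on the
FRAX-complete subset, emulating designs where probability calculators were
computable for only part of the cohort; nothing is imputed.

## Meta-analysis

Per-cohort log hazard ratios are pooled with inverse-variance fixed-effects
weights; the pooled risk ratio is `exp` of the weighted mean coefficient.
Cochran's Q and I² = max(0, (Q−(k−1))/Q)·100 accompany every pooled result
so the low-heterogeneity premise of fixed effects is checkable;
DerSimonian–Laird random-effects pooling is available as a labelled
sensitivity output. I² is defined as 0 when Q = 0 (including k = 1).

## Synthetic cohorts

The generator emulates a three-cohort study of community-dwelling older men
(labelled HK, SW, US) with published baseline characteristics: sample sizes
1662/1521/991; age 73.9±4.9, 79.5±3.4, 77.0±5.1 y; muscle density 77.0±3.6,
69.6±3.7, 70.5±4.6 mg/cm³; CSA 35.4±7.0, 38.9±7.4, 75.5±11.8 cm²; FN BMD
T-score −1.41±0.91, −0.92±1.02, −0.53±1.06; FRAX MOF probabilities with
their observed complete-case fractions (1382/1662, 976/1521, 478/991);
prior-fall prevalence 17.3/13.2/23.2%; follow-up 8.1±2.3, 5.3±2.0, 7.8±2.2 y
with person-years 13 541.8 / 8 057.5 / 7 777.5; and nested event counts
(e.g. HK 161 any / 125 osteoporotic / 94 MOF / 47 hip).

Design choices, in order of consequence:

* **Shared probability space.** Events are simulated month-by-month on the
  estimator's own grid with per-month probability `1 − exp(−λ/12)`; event
  times are recorded at the end of their month. Parameter recovery is then
  exact-in-expectation rather than discretization-limited. Fracture is
  evaluated before death within a month; subjects remain at risk for
  further fractures after a non-fatal one so that every outcome definition
  has a proper risk set.
* **Effect structure.** Generator effects are per within-cohort SD of the
  configured distribution. Defaults: density HR 0.80/SD and T-score HR
  0.70/SD directly on the all-fracture hazard, CSA with *no* direct effect.
  CSA then shows a marginal association (via its 0.30 correlation with
  T-score) that vanishes on BMD adjustment, reproducing as mechanism the
  attenuation contrast the analysis grid is designed to display.
* **Calibration.** The all-fracture intercept is solved so the expected
  crude rate matches the published events/person-years, correcting for the
  lognormal mean of the covariate part of the hazard and for hazard growth
  from aging during follow-up. Administrative follow-up is truncated normal
  on (0.5, max_followup]; its mean is solved so the *observed* follow-up
  E[min(death, censoring)] matches person-years/n, because published
  follow-up already reflects death truncation. Death is a flat competing
  hazard (2.0/3.5/2.7% per year — assumed healthy-cohort values; mortality
  is not reported in the baseline table).
* **Covariate structure.** A Gaussian copula with one assumed 7×7
  correlation matrix (unreported in the source literature; positive
  definite, exposed in the config) for age, BMI, CSA, density, T-score and
  the two FRAX probabilities; FRAX margins are moment-matched lognormals
  clipped to (0, 100]%. FRAX missingness is MCAR and joint for the two
  probabilities.
* **Sites.** Each fracture draws a site from a per-cohort categorical whose
  nested class shares (hip / other MOF / other osteoporotic / other) match
  the published outcome counts, with fixed within-class splits.
* **Seeding.** One master seed; cohort i uses sub-stream `seed·1000 + i`.
  Identical config + seed gives byte-identical CSV output.

What the generator does **not** emulate: fracture-site epidemiology beyond
category frequencies, age-dependent or frailty-correlated mortality,
informative loss to follow-up (loss is never generated by default),
non-proportional or time-varying exposure effects, secular/geographic
trends, and any measurement error in the exposures. Passing tests therefore
demonstrate the *estimator's* correctness and calibration under a
well-specified proportional-hazards world, not robustness of the scientific
conclusions to real-data violations of it.

## Numerical and testing choices

* Interval counts use `ceil(12T − 1e−9)` so float noise at exact month
  boundaries cannot create zero-length intervals.
* The ±20 separation bound, the 1e−10 relative-likelihood tolerance and the
  100-iteration cap were fixed from the scale of person-time hazards before
  any statistical experiments were run.
* Independent oracles: intercept-only fits against the closed form
  log(events/person-time); small random instances against a Nelder–Mead
  search over an independently coded likelihood; full fits against
  statsmodels GLM-Poisson with exposure; pooling against weighted least
  squares and statsmodels `combine_effects`. The implementation never
  delegates to these libraries.
* Problem sizes in the validation suite — three cohorts of 5000 over 50
  replicates for recovery, 200 simulations of 2000 for coverage — were
  chosen so Monte-Carlo error is comfortably below the tolerances being
  asserted while a full run stays in the minutes range on one CPU.

## Known limitations

* The Poisson likelihood treats the 0/1 monthly indicator as Poisson; at
  the hazards simulated here (≤ 3%/month) the Bernoulli/Poisson gap is far
  below estimation error, but the approximation would degrade for very
  high monthly hazards.
* Aggregating identical person-months before fitting (an equivalent-
  likelihood optimization) is not implemented; fits are fast enough
  without it.
* No left truncation, recurrent events, random-effects survival models,
  absolute-risk integration, or meta-regression.
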