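# Methods

This note documents the statistical model behind `hotpath`, the
assumptions baked into each stage, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate
about real surveys.

## Survey model and analysis frame

A survey is three linked CSV tables (households, persons, one-day trip
diary) plus a per-person walk/cycle frequency questionnaire with answers
in {several days per week, per month, per year, never} or missing.
The analysis frame keeps adults aged 18–65 — both bounds inclusive; the
bound convention is configurable because "18–65" is ambiguous — who are
complete cases on the model covariates. Education (six levels) is
dichotomised at post-secondary attainment (codes 5–6); car access at
zero household cars; residency at the inner-city zone.

Diary MET-hours use 3 METs for walking and 6 for cycling, constants
exposed in `survey_model.MET_VALUES`. Only trips whose *main* mode is
walk or cycle count: walking to or from a transit stop is not logged as
a walk trip in this survey design, and treating it otherwise would
change prevalence discontinuously across survey dialects.

## HOT metrics

Weighted estimators with Kish effective-sample-size normal confidence
intervals (`n_eff = (Σw)²/Σw²`, intervals clipped to [0, 1] for
proportions). Replicate-weight or bootstrap variance estimation is out
of scope; the single-stage approximation is adequate for the n ≈ 10⁴
surveys targeted here.

Two denominators deliberately differ: prevalence is computed over all
persons in scope, while participation is computed among questionnaire
respondents only (in the emulated survey about 54% of persons skip the
questionnaire). Frequency = prevalence/participation is therefore only a
within-subpopulation identity when both terms share a scope; the
estimators accept an explicit subgroup filter so callers can align
scopes when recovering latent parameters. Frequencies above 1 can occur
in small subgroups; they are reported as computed with a warning, and
truncated to 1 only inside the weekly scaling.

Intensity scales each *prevalent* person's diary MET-hours by `7·f_m`
per mode: the diary day is an unbiased draw of a participant's active
days, so diary activity × active days per week estimates weekly
activity. With a single combined `f` the algebraic identity
`TA = intensity × participation` holds to machine precision regardless
of how participation was estimated, because `f·participation =
prevalence` cancels exactly; with mode-specific `f_m` the identity is
only approximate. The weekly-scaling convention (diary × 7 × f) is an
interpretation of the one-day-to-week scaling described for these
metrics; it is asserted in tests via the identity above and via latent
parameter recovery, not against any external constant.

## Subgroup inference

Three models mirror the descriptive metrics: logistic regressions for
the prevalence and participation indicators, and ordinary least squares
on log weekly MET-hours ("log-linear") for intensity among weekly
participants with positive activity (zero-activity participants are
excluded because the log is undefined; this matches intensity's
definition over active travelers). Covariates: sex, age, education
(dichotomised), car access, inner-city residency.

Whether such survey analyses should weight regression models is
genuinely open; the default uses the survey weights as frequency weights
in the estimating equations with HC1 sandwich standard errors —
consistent with the weighted descriptive estimates — and `weighted=False`
reproduces the textbook fits exactly (verified against an independent
maximum-likelihood route). The weighted chi-squared test rescales the
weighted contingency table to the Kish effective sample size before
computing the ordinary Pearson statistic, so constant weights cancel
exactly.

## Scenario models

Travel Time Substitution: `δTA = α·t_o/60·(6 − 3γ_w)`, with `γ_w`
defaulting to the current walking share of active-travel time
`t_w/(t_w+t_c)`. A VMT-reduction policy is represented directly as a
fraction `α` of other-mode *time* — a deliberate simplification
(distance and time are treated as proportional at fixed speeds).

Mode Share Shift: `δTA = N/60·(3·t_w·δ_w + 6·t_c·δ_c)` with total trips
held constant (other modes absorb `−δ_w−δ_c`). Median rather than mean
trip durations are used because trip-duration distributions are heavily
right-skewed and a share shift moves typical trips. Exact invariants —
all-cycling replacement is exactly twice all-walking, linearity in every
policy lever, trip-delta conservation — are enforced in tests. Published
impact-table rows for the VMT scenario are mutually consistent only to
about one rounding unit, so cross-row checks use a 0.02 MET-h/week
tolerance.

## Comparative risk assessment

The exposure-response function is `R(x) = exp(−α·x^p)` on weekly
MET-hours. Fitting minimises squared residuals of log RR: for fixed `p`
the optimal `α` is closed-form, so a bounded 1-D search over `p` solves
the problem globally (a nonlinear refinement on the RR scale is
available). The bundled dose-response table transcribes pooled-cohort
hazard ratios with dose assigned at each category's *lower bound* (a
conservative convention) and the open-ended top category excluded (its
risk reversal is generally attributed to confounding and has no finite
dose). Under this protocol the fit lands within ~0.005/0.010 of the
reference parameters (0.107, 0.436); no standard midpoint convention
reproduces them exactly, and the source protocol is unpublished, so the
package defaults use the reference constants directly
(`RENNES_ERF`).

Baseline activity `x_b` is the median of a population simulated from
uniform draws within published activity intervals (default n = 10,000).
The bundled interval proportions are a synthetic stand-in for the
cohort's unpublished distribution, chosen once so the analytic mixture
median equals the published 12 MET-h/week; the simulation and its
analytic median are tested against each other for arbitrary specs.

`ρ = R(x_b + δTA)/R(x_b) − 1` evaluates the mortality change at the
population mean activity change — a shortcut justified by the
unobservability of the scenario activity distribution. A distributional
integrator is included as a diagnostic only. Since the power curve is
concave, the shortcut slightly overstates benefits for dispersed
changes; tests quantify the gap on uniform spreads (sub-0.005 at
realistic dispersions).

Averted DALYs use the zero-intercept regression of annual proportional
DALY-rate changes on death-rate changes (`k = Σxy/Σx²`, t-based CI;
default `k = 0.45`). This is an empirical bridge, not a causal pathway:
DALYs and deaths are umbrella metrics whose co-movement is used to scale
one proportional change into the other. Costs multiply averted DALYs by
a per-DALY cost; the bundled central/low/high rates (69,458 / 21,884 /
168,411 USD) are back-derived from a published impact table and the
bundled burden baselines (617 deaths, 57,700 DALYs per year) are
likewise derived, not a GBD extract — both are labelled as such in the
code and should be replaced with real inputs for new studies.

## Synthetic survey generator

The generator's latent model is: per mode, weekly participation
Bernoulli(π) with π logistic in residential zone and household car
access; active days per week for participants drawn from a truncated
binomial on 1..7; the diary day exchangeable across the week (no
day-of-week or seasonal structure, none being specified for the target
survey); trips on an active day zero-truncated Poisson with lognormal
durations; non-active modes plain Poisson. Survey weights are
independent lognormals with mean 1, so weighted and unweighted
estimators must agree in expectation — a tested invariant.

Walk and cycle participation are positively associated via a single
multiplicative factor on the joint probability, drawn conditionally so
the cycle marginal is preserved (clipping in extreme cells is accounted
for analytically in `expected_metrics`, which reproduces the sampler's
distribution exactly).

Questionnaire nonresponse is drawn independently up front as a response
class, and the class carries its own participation level. This is
informative (not-at-random) nonresponse, and it is forced by the
emulated survey's own headline figures: respondent-only mode
prevalences (46.1% walking) exceed the all-person overall prevalence
(24.7%), which is only possible if nonrespondents are far less active.
The default configuration calibrates, by deterministic root-finding at
construction time: respondent walking/cycling participation to
0.621/0.097 with their joint at 0.073 (overall 0.645), active-day
distributions to frequencies 0.742/0.371, inner-city share 0.1545,
zone/car-access odds ratios 2.7/5.6, nonresponse 0.54, and the
nonrespondent activity level such that the analytic overall prevalence
is exactly 0.247. Trip-model defaults (3 walk / 2 cycle trips on an
active day, lognormal durations with medians 13/15 minutes, 1.6×
inner-city activity multiplier, car/transit/other rates giving ~3 trips
per person-day) are realistic stylisations, not calibration targets.

What passing tests show: the estimators are unbiased for the latent
quantities under this generative model, at realistic sample sizes and
weight dispersion. What they do not show: robustness to real-survey
features the generator omits — day-of-week and seasonal structure,
household-correlated behaviour, misreported durations, weight raking to
demographic margins, and item (as opposed to questionnaire-level)
nonresponse.

## Problem sizes and numerical choices

Test and example runs generate ~7,800 households (~10,000 persons),
matching the emulated survey's scale; regression-recovery simulations
use n = 20,000. All randomness flows from explicit seeds
(`numpy.random.SeedSequence` sub-streams per table); a fixed seed makes
generated CSVs byte-identical. Root-finding uses Brent's method at
1e-12 tolerance; ERF fitting is a bounded scalar minimisation at 1e-12;
probability-vector validation tolerates 1e-9. Degenerate inputs (empty
scopes, zero participation, zero expected cells, perfect separation,
non-positive rates) raise typed errors rather than propagating NaNs.

## Known limitations

- Variance estimation ignores the survey's multi-stage design.
- The deaths→DALY bridge assumes the historical co-movement of the two
  rates transfers to activity-induced mortality changes.
- The ERF is age-invariant within 18–65; disease-specific pathways are
  out of scope.
- TTS treats VMT and travel time as interchangeable at fixed speeds;
  MSS holds total trips constant and excludes transit substitution.
- Costs are undiscounted single-year figures.
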