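# hotpath

Health-oriented transportation (HOT) analysis of active travel: from a
one-day household travel survey to population walking/cycling metrics,
policy scenario modelling, and a simplified comparative risk assessment
of the health and economic impacts.

The package is written for transport–health researchers and analysts who
have (or can emulate) a French EMD-style household travel survey —
households, persons, a single-day trip diary, and a walk/cycle frequency
questionnaire — and want defensible, reproducible estimates of how much
physical activity a population obtains through transport and what a
policy-induced change in that activity would be worth in averted deaths,
DALYs and costs.

## The model

**HOT metrics.** For each person the one-day diary yields active-travel
MET-hours (3 METs per walking hour, 6 per cycling hour). Five
survey-weighted metrics summarise a population:

- *prevalence* — share of persons with ≥ 1 walk/cycle trip on the diary
  day;
- *participation* — share reporting walking/cycling "several days per
  week" on the frequency questionnaire (respondents only);
- *frequency* — `f = prevalence / participation`, the fraction of days a
  weekly participant is actually active, and the factor that scales the
  single diary day to a week;
- *intensity* — mean weekly MET-hours among active travelers,
  `7 · f ·` diary MET-hours;
- *travel activity* — `TA = 7 ·` mean diary MET-hours over everyone,
  satisfying `TA = intensity × participation`.

Confidence intervals use a normal approximation on the Kish effective
sample size `n_eff = (Σw)² / Σw²`.

**Scenario models.** Two equations translate policy into a per-person
activity change δTA (MET-h/week):

- *Travel Time Substitution* (e.g. a 10% cut in vehicle miles traveled):
  `δTA = α · t_o/60 · (6 − 3·γ_w)`, where `t_o` is weekly minutes in
  non-active modes, `α` the replaced fraction and `γ_w` the walking
  share of the replaced time;
- *Mode Share Shift* (a mode-share target): `δTA = N/60 · (3·t_w·δ_w +
  6·t_c·δ_c)` with `N` weekly trips per person, `t_w`, `t_c` median trip
  durations, and `δ_w`, `δ_c` the share increments (total trips held
  constant).

**Health impacts.** All-cause mortality relative risk follows
`R(x) = exp(−α·x^p)` (defaults `α = 0.107`, `p = 0.436`, fitted to a
pooled-cohort dose–response table bundled with the package). With
baseline activity `x_b` (default 12 MET-h/week, the median of a
simulated activity distribution), a scenario's proportional mortality
change is `ρ = R(x_b + δTA)/R(x_b) − 1`. Averted deaths are
`|ρ| ×` annual deaths; averted DALYs use the empirical link `k ≈ 0.45`
between proportional changes in death and DALY rates (zero-intercept
regression on annual rate series); costs multiply averted DALYs by a
cost per DALY (central/low/high USD).

**Synthetic surveys.** Because real EMD microdata are licensed, a
generator produces surveys with known latent ground truth: weekly
participation is Bernoulli per mode (logistic in zone and car access),
participants have 1–7 active days per week, and the diary day is a
random weekday — so prevalence = participation × frequency holds by
construction and every estimator can be tested against analytic
expectations.

## Worked example

```python
import hotpath as hp

config = hp.default_rennes_config(n_households=7800)
survey, truth = hp.generate_survey(config)
frame = hp.build_analysis_frame(survey)          # adults 18-65

summary = hp.compute_hot_summary(frame)
change = hp.mss_delta_ta(hp.MssSpec(
    n_weekly_trips=23.1, t_med_w=12.0, t_med_c=15.0,
    delta_w=0.098, delta_c=0.059,                # mode-share target
))
impact = hp.assess_impact(change.delta_ta)
```

which, printed with the formatting below, gives:

```
persons surveyed        : 10013
analysis frame (18-65)  : 9427
one-day prevalence      : 0.244 (95% CI 0.235-0.253)
weekly participation    : 0.647 (95% CI 0.632-0.662)
frequency walk / cycle  : 0.38 / 0.19
delta TA (MSS)          : 3.40 MET-h/week
rho                     : -0.0357
averted deaths / DALYs  : 22 / 927
cost saved, central     : $64M ($20M-$156M)
```

Reading: on a random day ~24% of adults log a walk or cycle trip, while
~65% of questionnaire respondents report walking or cycling several days
a week — the frequency ratio (how many days per week a participant is
active) reconciles the two. Raising walk/cycle mode shares by 9.8/5.9
percentage points adds 3.4 MET-h of weekly activity per person, a 3.6%
drop in all-cause mortality risk, worth ~22 deaths and ~930 DALYs per
year in a population with 617 annual deaths among adults 18–65.

The same pipeline runs from a YAML configuration on the command line:

```bash
hotpath all --config config.yaml --out results/
```

writing `metrics.json`, regression tables (`table2.csv`), the scenario
impact table (`table3.csv`, `impact.json`), participant characteristics
(`table1.csv`), a mode-share chart and a reproducibility manifest.

## Education code book

Six-level education variable (French survey convention), dichotomised at
codes 5–6 ("highly educated"):

| code | label |
|------|-------|
| 1 | Primary School |
| 2 | Secondary, from 6th to 3rd |
| 3 | Secondary, beyond 2nd Without Completing Baccalaureate |
| 4 | Secondary Baccalaureate |
| 5 | Superior Baccalaureate, up to 2 |
| 6 | Superior Baccalaureate, 3+ OR Apprenticeship |

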