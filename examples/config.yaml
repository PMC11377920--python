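# Full-pipeline configuration on the bundled synthetic-survey preset.
#   hotpath all --config examples/config.yaml --out results/
generator_preset: rennes-2018
preset_n_households: 8000
seed: 2018

age_min: 18
age_max: 65
weighted: true

scenarios:
  # mode-share target: +9.8pp walking, +5.9pp cycling, trip counts and
  # median durations taken from the generated survey
  - name: mobility
    type: mss
    from_survey: true
    parameters:
      delta_w: 0.098
      delta_c: 0.059
  # 10% of other-mode travel time replaced entirely by cycling
  - name: climate_all_cycle
    type: tts
    from_survey: true
    parameters:
      alpha_replaced: 0.10
      gamma_w: 0.0
  # ... and entirely by walking
  - name: climate_all_walk
    type: tts
    from_survey: true
    parameters:
      alpha_replaced: 0.10
      gamma_w: 1.0

# annual baseline burden, adults 18-65 (derived example values)
burden:
  annual_deaths: 617
  annual_dalys: 57700
  population: 300000
  k_link: 0.45

# cost per averted DALY, USD
cost:
  usd_per_daly_central: 69458
  usd_per_daly_low: 21884
  usd_per_daly_high: 168411

baseline_activity: 12.0
out_dir: results
log_level: INFO
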