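# Base-case parameter document: fitted survival curves (time in months),
# health-state utilities, unit costs (2023 USD) and structural settings for
# the adjuvant osimertinib vs placebo cost-effectiveness model.
model:
  cycle_length_days: 21
  n_cycles: 275
  annual_discount_rate: 0.03
  start_age: 63
  life_expectancy_cap: 78.8
  half_cycle_correction: true
  treatment_cap_cycles: 52
  mode: markov

survival:
  dfs_active:            # log-logistic DFS, osimertinib arm
    family: loglogistic
    shape: 1.63351
    scale: 112.73457
  dfs_control:           # generalized-gamma DFS, placebo arm
    family: gengamma
    mu: 2.88767
    sigma: 1.45261
    Q: -1.30760
  os_active:             # generalized-gamma OS, osimertinib arm
    family: gengamma
    mu: 4.36038
    sigma: 1.26750
    Q: -3.13596
  os_control:            # log-normal OS, placebo arm
    family: lognormal
    meanlog: 4.83614
    sdlog: 1.01581

utilities:
  dfs: 0.83
  recurrence: 0.74
  death: 0.0

costs:
  osimertinib_per_80mg_day: 566.64
  pemetrexed_per_10mg: 7.51
  cisplatin_per_10mg: 3.17
  administration_per_cycle: 155.09
  imaging_per_event: 249.48
  laboratory_per_event: 340.20
  terminal_care_once: 10187.64
  physician_visit_per_event: 160.20
  bsc_per_cycle: 481.57
  body_surface_area: 1.82
  subsequent_therapy_fraction_active: 0.671
  subsequent_therapy_fraction_control: 0.663

# Explicit sensitivity ranges; every other uncertain parameter defaults to
# +/-20% of its baseline.
ranges:
  utility_dfs: [0.67, 0.99]
  utility_recurrence: [0.59, 0.89]
  discount_rate: [0.0, 0.05]

wtp: 150000
psa:
  n_draws: 1000
  seed: 20240328
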