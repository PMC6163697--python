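# CohortSpec schema: every field is optional and falls back to the library
# default. day_law / night_law follow the SegmentLaw fields.
n_subjects: 20
n_days: 1
sample_interval_s: 30      # 3 or 30 (any divisor of 86400 is accepted)
seed: 0
start_date: "2012-06-01"
alarm_clock_prob: 0.1      # fraction of subjects excluded by the alarm-clock rule
age_range: [0, 14]
inhabitants_choices: [800, 3500, 7500, 15000, 35000, 75000, 150000, 900000]
substation_probs: [0.9, 0.05, 0.05]   # >=40 m, <40 m, same building or adjacent
day_law:
  log10_mu: -1.62          # median segment level 0.024 µT
  log10_mu_sd: 0.20
  log10_sigma2: -5.3       # median in-segment noise (2.2 nT)^2
  log10_sigma2_sd: 0.50
  p_zero_sigma2: 0.0       # probability of an exactly constant segment
  phi_mean: 0.45
  phi_sd: 0.15
  phi_max: 0.95
  median_duration_samples: 200   # ~1.7 h at 30 s
  log10_duration_sd: 0.35
  min_duration_samples: 8
night_law:
  log10_mu: -1.75          # 0.018 µT: quieter nights
  log10_mu_sd: 0.15
  log10_sigma2: -6.4
  log10_sigma2_sd: 0.50
  phi_mean: 0.55
  phi_sd: 0.12
  median_duration_samples: 700   # ~5.8 h
  log10_duration_sd: 0.30
  min_duration_samples: 8
# optional subgroup level -> multiplier on segment mean level, e.g.
# mu_multipliers:
#   inhabitants:
#     "200000-1999999 inhab.": 1.6
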