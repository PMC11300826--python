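# Default-style study configuration; any SimulatorConfig field can be set here.
n_subjects: 27
n_baseline_laps: 2
hmi_laps:
  - "road_markings:distance"
  - "road_markings:light_change"
  - "hud_circle:distance"
  - "hud_circle:light_change"
course:
  n_lights_per_lap: 8
  n_yellow_per_lap: 4
  trigger_distance: 185.0
  light_spacing: 450.0
factors:
  - {name: goRT_all, mean: 618.148, sd: 170.594, sign_vs_yellow_speed: -1}
  - {name: upps_positive_urgency, mean: 6.630, sd: 2.0, sign_vs_yellow_speed: 1}
  - {name: dbq_ordinary_violations, mean: 13.556, sd: 4.348, sign_vs_yellow_speed: 1}
  - {name: bas_fun_seeking, mean: 11.704, sd: 2.165, sign_vs_yellow_speed: 1}
coefficients:
  - {factor: goRT_all, intercept: 17.36, beta_hmi: 3.69, beta_factor: 0.0,
     beta_interaction: -0.0147, random_intercept_sd: 2.69, residual_sd: 1.86}
  - {factor: upps_positive_urgency, intercept: 17.36, beta_hmi: -8.71, beta_factor: 0.0,
     beta_interaction: 1.23, random_intercept_sd: 2.69, residual_sd: 1.86}
  - {factor: dbq_ordinary_violations, intercept: 17.36, beta_hmi: -6.99, beta_factor: 0.0,
     beta_interaction: 0.473, random_intercept_sd: 2.69, residual_sd: 1.86}
  - {factor: bas_fun_seeking, intercept: 17.36, beta_hmi: -11.14, beta_factor: 0.0,
     beta_interaction: 0.9, random_intercept_sd: 2.69, residual_sd: 1.86}
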