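# Patient-wide model defaults (two-population competition model).
# Units: rates per day, carrying capacity in cells, times in days.
model:
  r_s: 0.0156          # sensitive growth rate
  r_r: 0.0091          # resistant growth rate
  beta_sc: 8.0         # cohort-wide growth-rate scaling factor
  alpha_rs: 6.0        # competitive effect of sensitive on resistant cells
  alpha_sr: 1.0        # fixed at the intra-type unit
  K: 10000.0           # shared carrying capacity
  treatment_drop: 0.9  # fractional K reduction of sensitive types on therapy
  conversion: 200.0    # cells per ng/ml PSA (median baseline PSA <-> K/2)

# Canonical simulation initial conditions (declared here, not taken from data):
# heavy initial burden near carrying capacity with a minority resistant clone.
simulation:
  initial_total_fraction_of_K: 0.70
  initial_resistant_fraction: 0.10
  horizon_days: 1800.0

protocol:
  kind: adaptive_ideal
  stop_fraction: 0.5       # stop after >50% PSA decline
  restart_fraction: 1.0    # restart at the pre-abiraterone baseline
  observation_interval_days: 28.0

progression_rule:
  psa_multiple: 1.2
  on_period_factor: 2.0

cohort:
  n_adaptive: 17
  n_continuous: 16
  noise_sigma: 0.1
  seed: 0

fit:
  beta_bounds: [1.0, 20.0]
  alpha_bounds: [0.5, 12.0]
  n_coarse: 7
  n_refine: 5
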