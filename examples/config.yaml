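# Annotated default configuration for the odormon CLI.
# Any key omitted falls back to these defaults; unknown keys are an error.

seed: 1                  # master seed for every source of randomness
folds: 10                # cross-validation folds (k selection, PLS components)
k_grid: [1, 3, 5, 7, 9]  # odd neighbour counts tried for the k-NN classifier
a_grid: null             # PLS component grid; null = 1..min(10, feasible)
k_sd: 3.0                # PCA score outlier threshold, in score SDs

window:                  # analysis-window split for feature extraction
  baseline_fraction: 0.2 # leading fraction averaged as pre-exposure baseline
  steady_fraction: 0.5   # trailing fraction averaged as steady-state level

monitoring:
  window_s: 600.0            # analysis window for stream classification, s
  min_duration_min: 10.0     # minimum odor-event duration, minutes
  max_gap: 2                 # tolerated interrupting windows inside an event
  source_bearing_deg: 0.0    # bearing of the source as seen from the receptor
  sector_half_angle_deg: 45.0  # wind-compatibility half-angle (closed sector)
  threshold_ou_eq: 300.0     # fenceline warning threshold, ou_eq
  area_type: residential_mixed  # or industrial_agricultural (10% / 15% limit)
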