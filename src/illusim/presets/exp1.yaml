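# Yaw-rotation experiment: 20 subjects, orientations 0, +/-30, +/-60 deg,
# mean eyeshadow shift +2.42% with no orientation or interaction effects.
name: exp1
rotation_axis: yaw
angles: [-60.0, -30.0, 0.0, 30.0, 60.0]
seed: 1
population:
  n_subjects: 20
  baseline_pse_mean: 100.0
  baseline_pse_sd: 1.0
  shadow_shift_mean: 2.42
  shadow_shift_sd: 1.0
  orientation_shift_means: {}
  orientation_shift_sd: 0.0
  interaction_shift_means: {}
  interaction_shift_sd: 0.0
  slope: 2.0
  lapse_rate: 0.02
  seed: null
staircase:
  level_min: 92.0
  level_max: 108.0
  step: 1.0
  start_ascending: 92.0
  start_descending: 108.0
  reversal_criterion: 6
  max_trials: 200
analysis:
  epsilon_method: cm
  bf_samples: 100000
  bf_method: auto
  r_fixed: 0.5
  r_random: 1.0
  alpha: 0.05
  pooling: pooled
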