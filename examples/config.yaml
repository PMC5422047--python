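# End-to-end demo configuration for `wearact run`.
# Source: 12-subject reference cohort at 15 Hz; transfer target: 48-subject
# six-activity cohort at 50 Hz in a rotated device frame.
cohort:
  n_subjects: 12
  sampling_rate_hz: 15.0
  duration_s: 15.0
  noise_sd: 0.05
  subject_offset_sd: 0.05
harmonize:
  target_rate_hz: 15.0
  median_kernel: 3
windows:
  width_s: 1.0
  step_s: 0.5
algorithms: [NB, 1NN, 3NN]
folds: 6
seed: 0
train:
  algorithm: NB
  top: 10
transfer:
  cohort:
    n_subjects: 48
    sampling_rate_hz: 50.0
    activities: [sitting, supine, lying_left, lying_right, standing, walking]
    rotation: {axes: [y, z, x]}
  harmonize:
    target_rate_hz: 15.0
    rotation: {axes: [z, x, y]}  # inverse of the device frame above
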