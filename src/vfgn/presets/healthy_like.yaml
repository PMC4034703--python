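# Agent preset: unimpaired-like navigator.
# Angles in degrees, lengths in meters. between_sd is the between-subject
# spread of each parameter within a cohort (clipped to valid ranges).
name: healthy_like
params:
  pointing_sd: 8.0
  memory_sd0: 12.0
  memory_decay: 0.75
  forget_sd: 0.2
  heading_sd: 6.0
  lapse_rate: 0.02
between_sd:
  pointing_sd: 3.0
  memory_sd0: 3.0
  memory_decay: 0.05
  forget_sd: 0.1
  heading_sd: 1.0
  lapse_rate: 0.02
age_slope_memory_sd0: 0.0
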