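# Agent preset: impaired-like navigator (noisier spatial memory, stronger
# trial-wise forgetting, more pure-exploration lapses than healthy_like).
name: impaired_like
params:
  pointing_sd: 12.0
  memory_sd0: 18.0
  memory_decay: 0.85
  forget_sd: 10.0
  heading_sd: 6.0
  lapse_rate: 0.12
between_sd:
  pointing_sd: 4.0
  memory_sd0: 5.0
  memory_decay: 0.05
  forget_sd: 0.3
  heading_sd: 1.0
  lapse_rate: 0.05
age_slope_memory_sd0: 0.0
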