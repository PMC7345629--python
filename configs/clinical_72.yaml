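n_positions: 72
trajectory_radius: 0.15
freq_grid:
  start: 1000000000.0
  stop: 8000000000.0
  num: 1001
time_grid:
  start: 0.0
  stop: 6.0e-09
  num: 700
breast_radius: 0.055
eps_breast: 6.4
eps_bg: 1.0
image_extent: 0.15
image_size: 500
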