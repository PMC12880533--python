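# Reference configuration: the default benchtop campaign.
seed: 0

scenario:
  geometry:
    block_mm: [30, 20, 10]
    channel_diameter: 2.5
    vessel_depth: 1.0
  actuator:
    diameter: 3.5
    power_mw: 56.7
  layout:
    lateral_offset: 3.5
    interlayer_spacing: 1.5
  ambient:
    ambient_temperature: 25.0
    convective_coefficient: 15.0
    bottom_surface_temperature: 25.0
    inlet_fluid_temperature: 25.0
  flow:
    mean_speed: 1.0
    profile: plug
  spacing: 0.5

dataset:
  depths: [1.0, 1.5, 2.0]
  flows: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  replicates: 50
  noise_sd: 0.002
  mode: temperature

model:
  hidden: [64, 64, 32]
  dropout: 0.1
  epochs: 600
  batch_size: 128
  learning_rate: 3.0e-3
  n_ensemble: 5

evaluation:
  folds: 5
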