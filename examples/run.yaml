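# Example pipeline configuration (all keys optional; defaults shown in
# cropdistill.pipeline.default_config). A small demo-sized run:
weather:
  n_grids: 12
  n_years: 10
  lat_min: 31.0
  lat_max: 42.0
  seed: 11
  scenario_weights:
    baseline: 0.55
    cool_summer: 0.2
    heat_anthesis: 0.2
    cold_region: 0.05
dataset:
  noise_amplitude: 0.001
  train_fraction: 0.75
  seed: 21
train:
  max_epochs: 10
  patience: 10
  batch_size: 64
  lr: 0.001
  seed: 31
saliency:
  n_maps: 100
  percentile: 10.0
  seed: 41
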