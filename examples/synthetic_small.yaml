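# Desk-scale synthetic two-section benchmark: train on section 1, hold out
# section 2.  Completes in about a minute on one CPU.
seed: 1
out_dir: runs/synthetic_small

simulate:
  n_rows: 16
  n_cols: 16
  n_genes: 60
  n_latent: 4
  spot_spacing_px: 32
  spatial_length_scale: 3.0
  image_encoding_strength: 1.0
  count_depth: 5000
  noise_dispersion: 10.0
  section_shift: 0.3

preprocess:
  patch_size: 64
  target_sum: 10000
  n_hvg: 30
  batch_correction: center_scale

train:
  train_on_section: 1
  epochs: 250
  batch_size: 128
  learning_rate: 0.001
  backbone_kind: tiny_cnn
  use_sat: true

eval:
  k_prime: 50
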