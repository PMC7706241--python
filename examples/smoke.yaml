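# Desk-scale end-to-end configuration: tiny models, few iterations.
# Omitted fields keep the full-scale defaults (see chdseg.pipeline.RunConfig).
chambers: [LV]
n_train_subjects: 3
n_test_subjects: 3
sad: true
phantom:
  n_slices: 3
  apical_empty_slice: false
preprocess:
  target_size: 32
fcn:
  filters: [4, 4, 4, 4, 4]
  input_size: 32
  dropout_rate: 0.0
train:
  epochs: 3
gan:
  out_size: 32
  gen_channels: [16, 8, 8]
  disc_channels: [8, 8, 16]
gan_train:
  iterations: 25
  checkpoint_every: 25
n_synthetic: 40
synthetic_take: 6
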