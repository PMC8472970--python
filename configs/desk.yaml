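# Desk-scale profile: small enough to train on one CPU in minutes.
seed: 0
phantom:
  height: 128
  width: 128
  n_trees: 4
  width_range: [1, 4]
network:
  base_width: 16
  upsample_mode: adaptive
  gating: true
train:
  epochs: 3
  batch_size: 32
patches:
  size: 48
  per_image: 200
tiles:
  size: 48
  stride: 24
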