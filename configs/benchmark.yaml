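# Benchmark-scale profile (GPU-scale budgets; listed for completeness).
seed: 0
phantom:
  height: 584
  width: 565
network:
  base_width: 32
  upsample_mode: adaptive
  gating: true
train:
  epochs: 200
  batch_size: 256
patches:
  size: 48
  per_image: 10480
tiles:
  size: 48
  stride: 24
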