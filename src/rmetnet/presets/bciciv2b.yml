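# 3-channel, two-class motor imagery at 250 Hz (GDF recordings required).
seed: 0
data:
  kind: hdf5
  path: null
model:
  preset: bciciv2b
train:
  batch_size: 64
  epochs: 500
  learning_rate: 0.0001
  weight_decay: 0.075
  lam: 1.0
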