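# Desk-scale synthetic benchmark: 4 subjects, 2 classes, 6 channels, 1 s trials.
seed: 0
data:
  kind: synthetic
  synth:
    n_subjects: 4
    trials_per_class: 40
    n_classes: 2
    n_channels: 6
    n_samples: 250
    fs: 250.0
    erd_depth: 0.8
    subject_shift: 0.3
    snr_db: 10.0
model:
  preset: synthetic-small
train:
  batch_size: 64
  epochs: 30
  learning_rate: 0.001
  weight_decay: 0.0
  lam: 1.0
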