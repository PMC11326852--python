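# Desk-scale pipeline: 8 synthetic dipeptides in fixed 15.5 A cells,
# 16^3 maps at d_min 2.0 / oversampling 2.0, 500 full-batch training steps.
n_examples: 8
generator:
  n_residues: 2
  residue_alphabet: [GLY, ALA, SER]
  seed: 11
builder:
  d_min: 2.0
  oversampling: 2.0
  mode: fixed_cell
  fixed_cell: [15.5, 15.5, 15.5]
model:
  grid: [16, 16, 16]
  patch: [4, 4, 4]
  seed: 0
training:
  epochs: 500
  batch_size: 8
  learning_rate: 0.001
  seed: 0
n_shells: 5
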