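# Full phantom study at reference-cohort scale (about 13 min on one CPU).
phantom:
  n_patients: 400
cnn:
  epochs: 200
rf:
  n_trees: 50
n_levels: 64
normalize: true
symmetric: false
split_fractions: [0.6, 0.1, 0.3]
n_boot: 1000
seed: 0
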