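# Reduced demo study: 8 participants, 24 AR / 24 IR trials, post-stimulus
# map region, 200 permutations (~1 min on one CPU). The package defaults
# (11 participants, 40/40/20/20 trials, full map range, 1000 permutations)
# emulate the full study and take a few minutes per run.
study:
  n_participants: 8
  n_trials_per_condition: {AR: 24, IR: 24, M: 8, CR: 8}
analysis:
  precision: float32
  map_enc_range: [0.0, 1.5]
  map_ret_range: [0.0, 2.0]
stats:
  n_permutations: 200
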