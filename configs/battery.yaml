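# The fixed synthetic battery: 20 American-style 7x7 mini puzzles solved by
# all eight factorial models.  time_limit is the simulated session limit for
# within-limit scoring, scaled from the original 25-min / 78-slot session to
# this battery's 22 slots at the same seconds-per-slot budget.
n_puzzles: 20
replicates: 10
time_limit: 423.0
fill_attempts: 50
synth:
  lexicon_size: 2400
  word_len_range: [3, 7]
  alphabet: ADEGILNORSTU
  clues_per_answer: 12
  ambiguity: 0.2
  dims: [7, 7]
  blocks: [[0, 3], [1, 3], [3, 0], [3, 1], [3, 5], [3, 6], [5, 3], [6, 3]]
  min_slot_len: 3
  seed: 0
  cluster_size: 6
  diagnostic_rate: 0.2
  borrow_rate: 0.08
  cluster_share: 0.5
  stock_pool_size: 2000
  tokens_per_answer: 4
  tokens_per_cluster: 6
  shared_pool_size: 40
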