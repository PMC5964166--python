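# Default co-expression patterns for the patterned-count simulator.
# Five patterns of 200 pseudogenes each, emulating the canonical benchmark
# shapes (sustained up, monotone down, monotone up, spike-and-return,
# decreasing up); Log2FC profiles are relative to the baseline group.
patterns:
  - id: A
    n_genes: 200
    profile: [2.0, 2.0, 2.0]      # sustained upregulation
  - id: B
    n_genes: 200
    profile: [-2.0, -3.0, -4.0]   # monotone downregulation
  - id: C
    n_genes: 200
    profile: [2.0, 3.0, 4.0]      # monotone upregulation
  - id: D
    n_genes: 200
    profile: [3.0, 0.0, 0.0]      # spike then return to baseline
  - id: E
    n_genes: 200
    profile: [4.0, 3.0, 2.0]      # strong up, decaying
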