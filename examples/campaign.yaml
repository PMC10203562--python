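# Demo campaign: small synthetic selection run that finishes in ~1 minute.
library:
  pattern: NNK
  n_positions: 4
  cells: 2.4e8
  efficiency: 0.017
  target_parental_frequency: 0.013
simulation:
  n_integrants: 50000
  rounds:
    best: 2
    display: 1
  gates:
    best:
      display_threshold: 1.0
      binding_threshold: 1.0
    display:
      display_threshold: 1.0
  n_cells_sorted: 10000
  depth: 20000
  per_base_error: 0.001
  seed: 1
enrichment:
  level: aa
  top: 8
flags:
  n_reference: 48
  n_descriptors: 55
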