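# Small demonstration pipeline: two selection arms, two rounds.
# Run:  bandselex pipeline --config examples/demo.yaml
outdir: bandselex_demo
seed: 1
simulation:
  library_size: 5000
  rounds: 2
  conditions:
    - {factor: POU1, bob1: false}
    - {factor: POU1, bob1: true}
  selection_stringency: 1.0
trim:
  anchor_length: 8
  max_anchor_mismatches: 1
pattern:
  word: ANNNNAAN
  count_mode: per_read
  strand_mode: both
  top: 100
comparisons:
  - [POU1+BOB1, POU1]
synthesize_intensities: true
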