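# Demo run: two phantom populations (flat WT-like vs twisted mutant-like),
# 18 individuals each, full simulate -> extract -> measure -> classify.
seed: 7
n_per_group: 18
jitter: 0.1
extract: true
noise_sd: 5.0
extraction: {}
groups:
  - label: WT
    spec:
      shape: twisted_slab
      length: 48
      width: 24
      thickness: 5
      twist: 0.0
  - label: mutant
    spec:
      shape: twisted_slab
      length: 48
      width: 24
      thickness: 5
      twist: 180.0
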