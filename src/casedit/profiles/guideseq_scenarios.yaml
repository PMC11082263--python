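# Default GUIDE-seq-lite scenarios: on/off-target read-weight structure for
# a promiscuous (SpCas9-like: many off-target sites) and a high-fidelity
# (SaCas9-like: few off-target sites) regime, scaled to a 100-kb synthetic
# genome. The configured off-index separation is 20x
# (0.4 vs 0.02 = total off weight / on weight).
spcas9_like:
  on_weight: 3000
  off_mismatches: [1, 2, 2, 3, 3, 3, 4, 4, 4, 4, 5, 5, 5, 5, 6, 6, 6, 6, 2, 3, 4, 5, 6, 1]
  off_weights: [50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50]

sacas9_like:
  on_weight: 3000
  off_mismatches: [2, 3, 3]
  off_weights: [20, 20, 20]
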