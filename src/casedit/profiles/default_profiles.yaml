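# Default repair-outcome profiles driving the allele simulator.
#
# The two profiles encode the qualitative contrast between a nuclease with
# a strong staggered-cut bias (SpCas9-like: frequent templated +1 NHEJ
# duplicating the -4 base) and one that cuts bluntly (SaCas9-like: the
# templated +1 fraction an order of magnitude lower, the remainder
# redistributed to -1 NHEJ and MMEJ). The numeric fractions are estimates
# read from published repair-spectrum panels, not measured constants, and
# are versioned here rather than hard-coded.
#
# "conditional" probabilities are conditional on the read being edited and
# must sum to 1. mh_length_weights spread MMEJ events over flanking-repeat
# lengths 1 (the X|X single-base case) through 5 nt.

spcas9_like:
  label: SpCas9-like
  p_unmodified: 0.10
  conditional:
    ins1_templated: 0.08
    ins1_random: 0.04
    del1_nhej: 0.12
    mmej: 0.30
    del_other: 0.46
    hdr: 0.0
    dsodn: 0.0
  mh_length_weights: {1: 0.20, 2: 0.30, 3: 0.20, 4: 0.15, 5: 0.15}
  del_other_mean: 8
  del_other_max: 30

sacas9_like:
  label: SaCas9-like
  p_unmodified: 0.10
  conditional:
    ins1_templated: 0.008
    ins1_random: 0.04
    del1_nhej: 0.152
    mmej: 0.36
    del_other: 0.44
    hdr: 0.0
    dsodn: 0.0
  mh_length_weights: {1: 0.20, 2: 0.30, 3: 0.20, 4: 0.15, 5: 0.15}
  del_other_mean: 8
  del_other_max: 30

# Knock-in variants: the same contrast with donor pathways enabled. The
# blunt-cutting profile converts roughly twice the edited reads to dsODN
# capture / HDR, mirroring the ~100% increase seen when templated +1 repair
# does not outcompete the donor pathways.
spcas9_like_knockin:
  label: SpCas9-like + donors
  p_unmodified: 0.10
  conditional:
    ins1_templated: 0.08
    ins1_random: 0.04
    del1_nhej: 0.11
    mmej: 0.27
    del_other: 0.40
    hdr: 0.05
    dsodn: 0.05
  mh_length_weights: {1: 0.20, 2: 0.30, 3: 0.20, 4: 0.15, 5: 0.15}
  del_other_mean: 8
  del_other_max: 30

sacas9_like_knockin:
  label: SaCas9-like + donors
  p_unmodified: 0.10
  conditional:
    ins1_templated: 0.008
    ins1_random: 0.04
    del1_nhej: 0.122
    mmej: 0.29
    del_other: 0.34
    hdr: 0.10
    dsodn: 0.10
  mh_length_weights: {1: 0.20, 2: 0.30, 3: 0.20, 4: 0.15, 5: 0.15}
  del_other_mean: 8
  del_other_max: 30
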