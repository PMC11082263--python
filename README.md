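# casedit

Desk-scale analysis toolkit for comparing CRISPR nucleases by their repair
outcomes and genome-wide specificity — the computational layer of an
SpCas9-versus-SaCas9 comparison, built as a tested, reusable library with a
packaged repair-outcome simulator.

## Who this is for and what it does

Amplicon deep sequencing after Cas9 editing yields allele tables: indel
descriptors plus read counts. GUIDE-seq-style assays yield junction reads
that mark double-strand-break sites genome-wide through capture of a blunt
34-bp double-stranded oligodeoxynucleotide (dsODN). `casedit` turns both
into the quantities used to compare nucleases:

* **Cut-anchored repair classification.** Every allele is assigned one of:
  templated +1 NHEJ (a single-base insertion at the cut duplicating the
  fourth nucleotide upstream of the PAM — the hallmark of a 1-nt staggered
  cut filled in before ligation), −1 NHEJ, other insertions/deletions, MMEJ
  (deletions flanked by 2–5 nt microhomologies, plus the single-base X|X
  case such as G deleting in G|G), HDR (an exact donor insert at the cut),
  forward/reverse dsODN integration, or complex. Relative frequencies are
  fractions of *edited* reads.
* **Target modelling.** PAM scanning with IUPAC degenerate motifs (NGG for
  SpCas9, NNGRRT for SaCas9, R = A/G), dual-compatible NGGRRT sites that
  both nucleases can cut, spacer-length variants with the matched-G /
  mismatched-g 5′ rule required by U6-driven transcription, and PAM
  subtype labels (NNGGGT/NNGAGT/NNGAAT/NNGGAT).
* **GUIDE-seq-lite off-target calling.** dsODN tag detection in reads,
  exact-match flank mapping, single-linkage clustering into sites,
  protospacer matching up to 6 mismatches (Hamming, PAM recorded but not
  filtered), and the **off-index**:

  `off_index = total off-target reads / on-target reads`,

  a scale-free per-guide specificity statistic.
* **Comparison statistics.** Per-target normalization (each target divided
  by its best spacer-length mean), fold changes, Pearson r², paired /
  unpaired t and Wilcoxon matched-pairs tests.
* **Synthetic data.** Multinomial repair-profile simulation (packaged
  SpCas9-like and SaCas9-like defaults in versioned YAML), error-bearing
  read rendering, and random genomes with spacer-like windows planted at
  exact Hamming distances — every input the pipeline consumes.

All coordinates are 0-based, half-open, plus-strand (see
`docs/FORMATS.md`); the model details live in `docs/methods.md`.

## Worked example

```python
from casedit import ClassifyContext, classify_table, indel_frequency
from casedit import simulate as sim

site = sim.make_demo_site("SpCas9", seed=0)          # -4 base is A
profiles = sim.load_profiles()
alleles = sim.simulate_alleles(site, profiles["spcas9_like"], 10_000, seed=0)
ctx = ClassifyContext(hdr_insert=sim.HDR_INSERT, dsodn=sim.DSODN, window=10)
table = classify_table(site, alleles, ctx)
print(indel_frequency(table))
print(table.relative_frequencies)
```

Running `python examples/02_repair_outcomes.py` prints (seed 0):

```
SpCas9-like: indel frequency 0.896
  NHEJ_DEL_OTHER          0.4633
  MMEJ                    0.2974
  NHEJ_DEL1               0.1185
  NHEJ_INS1_TEMPLATED     0.0802
  NHEJ_INS_OTHER          0.0406

SaCas9-like: indel frequency 0.896
  ...
  NHEJ_INS1_TEMPLATED     0.0080

templated +1 fold separation (staggered/blunt): 10.0x
```

The templated +1 fraction — 8.0% of edited reads under the staggered-cut-
biased profile versus 0.8% under the blunt-cut-biased one — is the
simulator's configured order-of-magnitude contrast, recovered here by the
classifier from raw allele tables. The other examples cover PAM spacing
(`01`), end-to-end off-target calling with the off-index (`03`), and
spacer-length statistics (`04`).

A thin CLI mirrors the library (`casedit pamscan|classify|offtarget|
simulate|stats|run`); `casedit run --config cfg.yaml --out dir/` executes
the whole simulate → classify → stats → off-target pipeline with
byte-reproducible outputs.

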