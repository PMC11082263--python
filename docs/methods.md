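# Methods

## Scope and model

`casedit` analyses amplicon-sequencing allele tables and GUIDE-seq-style
junction reads at desk scale. Its central model is geometric: blunt Cas9
cleavage is placed 3 bp 5′ of the PAM, i.e. at the boundary between
PAM-relative protospacer positions −4 and −3, for both SpCas9 and SaCas9.
A 1-nt 5′-staggered cut at the same locus, filled in before ligation,
duplicates the −4 base; a single-base insertion of exactly that base at the
cut is therefore treated as the diagnostic signature of staggered cleavage
(templated +1 NHEJ). SaCas9's cut geometry is not independently
established here; the shared blunt boundary is adopted for symmetry and
because the −4-duplication diagnostic requires a fixed reference boundary.
All coordinates are 0-based, half-open, plus-strand; minus-strand sites
carry a strand flag and report protospacer-strand-oriented sequences.

## Classification cascade

Alleles are lists of non-overlapping indels with read counts. Before
classification each indel is canonicalised: among alignment-equivalent
placements (shifting through repeat context preserves the alternative
sequence) the placement closest to the cut is chosen, leftmost on ties.
Left-alignment alone misplaces homopolymer events relative to the cut,
and every rule below is cut-relative.

The cascade (first match wins) over the indels overlapping the
quantification window:

1. nothing in the window → `UNMODIFIED`;
2. a single insertion at the cut equal to the donor insert → `HDR`;
3. any insertion containing a ≥ 20-nt exact substring of the dsODN (or its
   reverse complement) → `DSODN_FWD`/`DSODN_REV`;
4. a single 1-nt insertion at the cut duplicating the −4 base (compared in
   protospacer-strand orientation, so the call is strand-invariant) →
   `NHEJ_INS1_TEMPLATED`;
5. any other single insertion → `NHEJ_INS_OTHER`;
6. a single deletion with a 2–5 nt flanking repeat (longest repeat,
   left-side form preferred; both symmetric forms checked), or a 1-nt
   deletion at the cut of a base equal to the base across the boundary
   (the X|X case) → `MMEJ`;
7. any other single 1-nt deletion → `NHEJ_DEL1` (so deleting G in a T|G
   context is −1 NHEJ, not MMEJ);
8. any other single deletion → `NHEJ_DEL_OTHER`;
9. anything else (multiple indels in the window) → `COMPLEX`.

Design choices where the convention was genuinely open:

* **Quantification window ± 10 nt.** Wide enough to cover realistic
  cut-proximal allele spectra, narrow enough to ignore distal noise.
  Indels entirely outside the window are ignored (a distal-only allele is
  `UNMODIFIED`); rules 2–9 see only window-overlapping indels.
* **Template-specific signatures outrank indel shapes.** HDR and dsODN
  matches are long and sequence-specific; the generic insertion/deletion
  rules only apply when they fail.
* **dsODN threshold 20 nt.** Tolerates junctional trimming of the 34-nt
  tag while keeping the chance-match probability (4⁻²⁰ per window)
  negligible.
* **HDR is exact.** Only the complete donor insert at the cut with intact
  flanks counts; partial conversions fall through to other classes.
* **Substitutions are not called.** Alignment records indels only; a
  substitution-bearing read with no indel in the window is `UNMODIFIED`.

Relative frequencies divide per-class read counts by edited reads
(total − unmodified); an all-unmodified table yields an explicit empty
result rather than 0/0. An alternative statistic over the top-N most
frequent edited alleles is exposed
(`ClassifiedTable.top_allele_relative_frequencies`) for workflows that
quantify only the dominant alleles; the edited-read fraction is the
default.

Alignment (`align_allele`) uses Needleman–Wunsch global alignment with
match +2, mismatch −1, gap open −5, gap extend −1 (Biopython's
`PairwiseAligner`); the first optimal path is taken and indels are then
re-anchored as above, which removes the path ambiguity that matters for
classification.

## Off-target stage

Junction reads are screened for the dsODN tag in either orientation with
at most 2 mismatches (exact match fast path); the longer genomic flank
(≥ 25 nt) is kept. Flanks are exact-matched to the genome on both strands;
multi-mapping flanks are dropped (determinism over recall). Integration
positions within 25 nt merge by single linkage; the cluster representative
is the minimum coordinate. Around each cluster the best protospacer-length
window within a 25-nt radius on either strand is chosen by Hamming
distance over protospacer positions only — the PAM-adjacent sequence is
reported for display but never filters candidates — and sites beyond 6
mismatches are not reported. Ties break by proximity, then plus strand,
then leftmost. The on-target site is the one overlapping the declared
target coordinate when given, otherwise the 0-mismatch site; among
candidates the highest read count wins so exactly one site carries the
flag. The off-index divides total off-target reads by on-target reads and
is invariant under uniform read-count scaling. Read counts are raw
junction-read counts: no UMI consolidation, bidirectional consistency
test, or genome-scale alignment — deliberate divergences from production
GUIDE-seq, matched to the simulator, which emits reads rather than
molecules.

## Statistics

Per-target normalization divides each measurement by the maximum
spacer-length *mean* for that target (per nuclease, optionally per cell
type) — a per-condition efficiency rather than a single-replicate maximum
— making the per-target maximum 1 and the values scale-invariant.
Cross-nuclease normalization (`normalize_to_reference`) exposes both a
per-target and a global reference mean, since either convention is
defensible. Fold change is a ratio of group means. Significance uses
paired/unpaired t-tests and the Wilcoxon matched-pairs test (exact
enumeration below 10 non-zero differences, normal approximation from 10);
a paired t on identical vectors returns (0, 1) explicitly, and an all-zero
Wilcoxon difference vector raises. No multiple-testing correction is
applied; results are per-comparison.

## Synthetic data: what it emulates and what it does not

`RepairProfile` draws outcomes from a multinomial over {unmodified,
templated +1, random +1, −1 NHEJ, MMEJ, other deletion, HDR, dsODN} and
renders each as a concrete indel: templated +1 inserts the −4 base at the
cut; MMEJ deletions are taken from a per-site catalogue of deletions with
planted 2–5 nt flanking repeats (weights over repeat lengths 1–5, length 1
being the X|X case); other deletions draw geometric lengths (mean 8 nt,
truncated at 30 — amplicon indel spectra are short-deletion-dominated and
no specific distribution is established) at cut-touching offsets. Every
rendered descriptor is verified against the classifier before emission and
re-drawn deterministically on collision (e.g. an accidental
microhomology), so generator labels and classifier calls agree by
construction on error-free input — which is what makes parameter-recovery
tests meaningful consistency checks rather than estimates of real-data
accuracy.

The packaged defaults put the templated +1 conditional fraction at 0.08
(SpCas9-like) versus 0.008 (SaCas9-like) — an order-of-magnitude
separation, with the blunt-cut profile's representative share below 1% of
edited reads and the difference redistributed slightly toward −1 NHEJ and
MMEJ; `p_unmodified = 0.10` reflects high-efficiency editing. These are
panel-derived estimates versioned in
`src/casedit/profiles/default_profiles.yaml`, not measured constants.

The demonstration amplicon is engineered, not sampled: its protospacer
core fixes −4 = A, A|A across the cut, and repeat copies on both sides of
the cut so MMEJ deletions of every length class exist; flanks are seeded
random sequence. Planted off-target genomes substitute spacer-derived
windows (exact Hamming distances, verified post hoc, with a nothing-better-
nearby check within the search radius) plus a concrete PAM into uniform
random sequence, with ≥ 400 bp separation. GUIDE-seq read counts are
Poisson per site; junction reads are error-free flank+tag concatenations.
The packaged scenarios configure a 20-fold off-index separation (0.4
versus 0.02) with many (24) versus few (3) off-target sites, scaled to a
100-kb genome.

Not modelled: sequencing error beyond i.i.d. substitutions, PCR bias and
chimeras, UMI structure, real genome composition (repeats, chromatin),
translocations, or large structural variants. Passing tests therefore
demonstrate internal consistency and correct statistics on data with the
assumed structure, not classifier performance on real amplicon libraries.

## Numerical and reproducibility choices

Problem sizes: 10,000 reads per profile for recovery runs, 100-kb planted
genomes, 300–400-kb Monte-Carlo sequences in tests and 1 Mb in the
acceptance script — sizes at which multinomial/Poisson bounds are tight
enough to be meaningful while runs stay in seconds. Parameter-recovery
tests use 99% multinomial bounds (z = 2.576 with a 1/n continuity term);
Monte-Carlo PAM counts allow 4σ because overlapping motif windows are
positively correlated, so the binomial σ understates the truth slightly.
All generators take explicit integer seeds; composite runs derive child
seeds via `SeedSequence([seed, stream])` (kept below 2³¹), and identical
(config, seed) pipeline runs are byte-identical. Degenerate inputs are
explicit errors rather than silent defaults: zero-variance correlation,
zero denominators, all-zero Wilcoxon differences, spacers extending past
the amplicon, missing on-target sites.

## Known limitations

Exact-match flank mapping cannot tolerate sequencing errors in the flank;
the off-target stage is validated on error-free junction reads. The
classifier tracks indels only, so mixed substitution/indel alleles are
`COMPLEX` at best. The MMEJ rule set follows the two worked conventions
(X|X is MMEJ; T|G-style −1 is NHEJ) and a 2–5 nt repeat range; repair
pathways do not partition this cleanly in reality. Off-index values depend
on raw read counts and are comparable only within a consistent protocol.
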