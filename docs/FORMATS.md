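# File formats

One convention end to end: every genomic interval in every file is
**0-based, half-open**, on the plus strand, with explicit `strand`
columns. TSV files are tab-separated with a header row, UTF-8, and `.` for
missing values.

## FASTA / FASTQ

Standard multi-record FASTA (wrapped or unwrapped) for amplicons and
genomes. FASTQ is fixed 4-line-per-record; qualities are read but ignored.
Malformed framing raises an error naming the offending line and read.

## Site tables (`sites.tsv`)

| column | meaning |
|---|---|
| target_name | site label |
| amplicon_id | FASTA record the coordinates refer to |
| nuclease | SpCas9 or SaCas9 |
| strand | protospacer strand, `+`/`-` |
| protospacer_start, protospacer_end | plus-strand interval |
| protospacer_seq | protospacer-strand oriented |
| pam_seq | 6-mer 3' of the protospacer, protospacer-strand oriented |
| pam_class | NNGGGT/NNGAGT/NNGAAT/NNGGAT, or `.` |
| cut_index | plus-strand boundary coordinate of the blunt cut |

## Allele tables (`alleles.tsv`)

Columns: `allele_id`, `read_count`, `n_deleted`, `n_inserted`,
`indel_descriptor`, `aligned_sequence` (optional, `.` if absent).

`indel_descriptor` is `;`-joined descriptors: `DEL:<ref_start>:<length>`
or `INS:<ref_start>:<length>:<bases>`; `.` means no indel. Insertions sit
*before* reference position `ref_start`.

Classified tables add `class` and `relative_frequency` (fraction of
edited reads; `.`/NaN for unmodified rows), plus a JSON summary with
totals and per-class relative frequencies.

## Off-target site tables (`offtarget_sites.tsv`)

Columns: `chrom`, `position` (cluster representative = minimum junction
coordinate), `strand` (matched protospacer strand), `read_count`,
`matched_seq`, `pam_seq`, `mismatch_count`, `mismatch_string` (matching
bases as `.`, mismatched genomic base letter otherwise), `is_on_target`.

## Experiment record tables

Columns: `nuclease`, `target_name`, `cell_type`, `spacer_length`,
`replicate`, `indel_frequency` (fraction in [0,1]), optional `pam_class`.

## Configuration (YAML)

`RunConfig` keys: `seed`, `profile`, `n_reads`, `window`, `hdr_insert`,
`dsodn`, `guideseq_scenario`, `genome_len`, `cluster_window`,
`max_mismatches`, `search_radius`, `dsodn_match_length`. Unknown keys are
rejected. A run directory contains the resolved configuration
(`resolved_config.yaml`), which is sufficient to reproduce the run
byte-for-byte.
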