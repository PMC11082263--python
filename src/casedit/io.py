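"""Format readers/writers: FASTA, FASTQ, and the pipeline's TSV dialects.

TSV dialect: tab-separated, header row, UTF-8, '.' for missing values.
All genomic intervals in every file are 0-based half-open with explicit
strand columns (see docs/FORMATS.md).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import Allele, format_indels, parse_indels
from .offtarget import OffTargetSite
from .site_model import TargetSite, classify_pam, protospacer_seq
from .stats import ExperimentRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "write_json",
    "alleles_to_frame",
    "frame_to_alleles",
    "read_allele_table",
    "write_allele_table",
    "site_table",
    "write_site_table",
    "offtarget_table",
    "read_experiment_records",
    "write_experiment_records",
]

MISSING = "."


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping of record id -> upcased sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality) tuples from a 4-line-per-record FASTQ file.

    Framing errors raise with the offending line number and read name.
    """
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: line {i + 1}: expected '@' header, got {head[:30]!r}")
        if not plus.startswith("+"):
            raise ValueError(
                f"{path}: line {i + 3}: read {head[1:].split()[0]!r}: expected '+' separator"
            )
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: line {i + 4}: read {head[1:].split()[0]!r}: sequence/quality length mismatch"
            )
        out.append((head[1:].split()[0], seq.upper(), qual))
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[MISSING], keep_default_na=False, dtype=None
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def _json_default(o):
    import numpy as np

    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


# --- allele tables ---------------------------------------------------------


def alleles_to_frame(alleles: Sequence[Allele]) -> pd.DataFrame:
    rows = []
    for k, al in enumerate(alleles):
        rows.append(
            {
                "allele_id": al.allele_id or f"A{k + 1}",
                "read_count": al.read_count,
                "n_deleted": sum(i.length for i in al.indels if i.kind == "DEL"),
                "n_inserted": sum(i.length for i in al.indels if i.kind == "INS"),
                "indel_descriptor": format_indels(al.indels) or MISSING,
                "aligned_sequence": al.sequence if al.sequence else MISSING,
            }
        )
    return pd.DataFrame(rows)


def frame_to_alleles(df: pd.DataFrame) -> list[Allele]:
    alleles = []
    for row in df.itertuples():
        seq = getattr(row, "aligned_sequence", None)
        if isinstance(seq, float) or seq in (MISSING, None, ""):
            seq = None
        desc = row.indel_descriptor
        if isinstance(desc, float):  # '.' parsed as missing
            desc = ""
        alleles.append(
            Allele(
                indels=parse_indels(str(desc)),
                read_count=int(row.read_count),
                allele_id=str(row.allele_id),
                sequence=seq,
            )
        )
    return alleles


def write_allele_table(alleles: Sequence[Allele], path: str | Path) -> None:
    write_tsv(alleles_to_frame(alleles), path)


def read_allele_table(path: str | Path) -> list[Allele]:
    return frame_to_alleles(read_tsv(path))


# --- site / off-target / experiment tables ---------------------------------


def site_table(sites: Sequence[TargetSite], amplicon_id: str = "amplicon") -> pd.DataFrame:
    rows = []
    for s in sites:
        try:
            pam_class = classify_pam(s.pam)
        except ValueError:
            pam_class = MISSING
        rows.append(
            {
                "target_name": s.name or MISSING,
                "amplicon_id": amplicon_id,
                "nuclease": s.nuclease,
                "strand": s.strand,
                "protospacer_start": s.protospacer_start,
                "protospacer_end": s.protospacer_end,
                "protospacer_seq": protospacer_seq(s),
                "pam_seq": s.pam,
                "pam_class": pam_class,
                "cut_index": s.cut_index,
            }
        )
    return pd.DataFrame(rows)


def write_site_table(sites: Sequence[TargetSite], path: str | Path, amplicon_id: str = "amplicon") -> None:
    write_tsv(site_table(sites, amplicon_id), path)


def offtarget_table(sites: Sequence[OffTargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "position": s.position,
                "strand": s.strand,
                "read_count": s.read_count,
                "matched_seq": s.matched_protospacer,
                "pam_seq": s.pam_seq,
                "mismatch_count": s.mismatch_count,
                "mismatch_string": s.mismatch_string,
                "is_on_target": s.is_on_target,
            }
            for s in sites
        ]
    )


def read_experiment_records(path: str | Path) -> list[ExperimentRecord]:
    df = read_tsv(path)
    out = []
    for row in df.itertuples():
        pam = getattr(row, "pam_class", None)
        if isinstance(pam, float) or pam in (MISSING, None, ""):
            pam = None
        out.append(
            ExperimentRecord(
                nuclease=str(row.nuclease),
                target_name=str(row.target_name),
                cell_type=str(row.cell_type),
                spacer_length=int(row.spacer_length),
                replicate=str(row.replicate),
                indel_frequency=float(row.indel_frequency),
                pam_class=pam,
            )
        )
    return out


def write_experiment_records(records: Sequence[ExperimentRecord], path: str | Path) -> None:
    from .stats import records_to_frame

    write_tsv(records_to_frame(records), path)
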