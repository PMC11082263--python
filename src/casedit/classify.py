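"""Cut-site-anchored repair-outcome classification of amplicon alleles.

Every edited allele is assigned exactly one repair class by a fixed
decision cascade (first match wins):

1. no indel overlapping the quantification window -> UNMODIFIED
2. single insertion of the exact donor insert at the cut -> HDR
3. insertion carrying a long exact dsODN substring -> DSODN_FWD / DSODN_REV
4. single 1-nt insertion at the cut duplicating the -4 base -> templated +1
   NHEJ (the staggered-cut hallmark)
5. any other single insertion -> NHEJ_INS_OTHER
6. single deletion with a 2-5 nt flanking microhomology, or a 1-nt deletion
   of a base identical to the base across the cut (the X|X case) -> MMEJ
7. any other single 1-nt deletion -> NHEJ_DEL1
8. any other single deletion -> NHEJ_DEL_OTHER
9. everything else (multiple indels) -> COMPLEX

Longer, template-specific signatures (HDR, dsODN) outrank generic indel
shapes because they are more specific. Before classification each indel is
re-anchored cut-proximally: among alignment-equivalent placements (e.g. a
deletion inside a homopolymer) the placement closest to the cut is chosen,
so the cut-relative rules see a canonical representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import pandas as pd
from Bio import Align

from .seqcore import as_seq, find_microhomology, revcomp
from .site_model import TargetSite, minus4_base

__all__ = [
    "RepairClass",
    "Indel",
    "Allele",
    "ClassifyContext",
    "ClassifiedTable",
    "parse_indels",
    "format_indels",
    "apply_indels",
    "align_allele",
    "reanchor_indel",
    "classify_allele",
    "classify_table",
    "indel_frequency",
]


class RepairClass(str, Enum):
    UNMODIFIED = "UNMODIFIED"
    NHEJ_INS1_TEMPLATED = "NHEJ_INS1_TEMPLATED"
    NHEJ_INS_OTHER = "NHEJ_INS_OTHER"
    NHEJ_DEL1 = "NHEJ_DEL1"
    NHEJ_DEL_OTHER = "NHEJ_DEL_OTHER"
    MMEJ = "MMEJ"
    HDR = "HDR"
    DSODN_FWD = "DSODN_FWD"
    DSODN_REV = "DSODN_REV"
    COMPLEX = "COMPLEX"


#: Classes counted as edited (everything except UNMODIFIED).
EDITED_CLASSES = tuple(c for c in RepairClass if c is not RepairClass.UNMODIFIED)


@dataclass(frozen=True)
class Indel:
    """One insertion or deletion on the plus strand of the amplicon.

    INS: ``length`` bases of ``inserted_seq`` inserted before reference
    position ``ref_start``. DEL: reference interval
    ``[ref_start, ref_start+length)`` removed.
    """

    kind: str  # "INS" | "DEL"
    ref_start: int
    length: int
    inserted_seq: str = ""

    def __post_init__(self):
        if self.kind not in ("INS", "DEL"):
            raise ValueError(f"indel kind must be INS or DEL, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "INS" and len(self.inserted_seq) != self.length:
            raise ValueError("inserted_seq length must equal INS length")
        if self.kind == "DEL" and self.inserted_seq:
            raise ValueError("DEL carries no inserted_seq")

    def interval(self) -> tuple[int, int]:
        """Reference footprint: DEL covers its interval, INS is a point."""
        if self.kind == "DEL":
            return (self.ref_start, self.ref_start + self.length)
        return (self.ref_start, self.ref_start)


@dataclass(frozen=True)
class Allele:
    """An observed allele: sorted non-overlapping indels plus a read count."""

    indels: tuple[Indel, ...]
    read_count: int
    allele_id: str = ""
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        inds = tuple(sorted(self.indels, key=lambda i: (i.ref_start, i.kind)))
        object.__setattr__(self, "indels", inds)
        prev_end = -1
        for ind in inds:
            lo, hi = ind.interval()
            if lo < prev_end:
                raise ValueError("indel intervals overlap")
            prev_end = max(hi, lo)


@dataclass(frozen=True)
class ClassifyContext:
    """Classification parameters: optional HDR donor insert and dsODN
    sequences, the quantification window half-width around the cut (nt),
    and the minimum exact dsODN substring length for integration calls."""

    hdr_insert: Optional[str] = None
    dsodn: Optional[str] = None
    window: int = 10
    dsodn_min_match: int = 20

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.dsodn_min_match <= 0:
            raise ValueError("dsodn_min_match must be > 0")


# --- indel descriptor strings ("DEL:57:4", "INS:60:1:A") ------------------


def format_indels(indels: Iterable[Indel]) -> str:
    parts = []
    for ind in indels:
        if ind.kind == "DEL":
            parts.append(f"DEL:{ind.ref_start}:{ind.length}")
        else:
            parts.append(f"INS:{ind.ref_start}:{ind.length}:{ind.inserted_seq}")
    return ";".join(parts)


def parse_indels(descriptor: str) -> tuple[Indel, ...]:
    if descriptor in ("", "."):
        return ()
    out = []
    for part in descriptor.split(";"):
        fields = part.split(":")
        if fields[0] == "DEL" and len(fields) == 3:
            out.append(Indel("DEL", int(fields[1]), int(fields[2])))
        elif fields[0] == "INS" and len(fields) == 4:
            out.append(Indel("INS", int(fields[1]), int(fields[2]), as_seq(fields[3])))
        else:
            raise ValueError(f"malformed indel descriptor {part!r}")
    return tuple(out)


def apply_indels(ref: str, indels: Iterable[Indel]) -> str:
    """Render the allele sequence implied by a sorted indel list."""
    out = []
    pos = 0
    for ind in sorted(indels, key=lambda i: i.ref_start):
        out.append(ref[pos : ind.ref_start])
        if ind.kind == "INS":
            out.append(ind.inserted_seq)
            pos = ind.ref_start
        else:
            pos = ind.ref_start + ind.length
    out.append(ref[pos:])
    return "".join(out)


# --- alignment and placement canonicalisation ------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def _shift_left(ref: str, ind: Indel) -> Optional[Indel]:
    if ind.kind == "DEL":
        s, L = ind.ref_start, ind.length
        if s > 0 and ref[s - 1] == ref[s + L - 1]:
            return replace(ind, ref_start=s - 1)
    else:
        p = ind.ref_start
        if p > 0 and ind.inserted_seq[-1] == ref[p - 1]:
            return replace(
                ind, ref_start=p - 1, inserted_seq=ref[p - 1] + ind.inserted_seq[:-1]
            )
    return None


def _shift_right(ref: str, ind: Indel) -> Optional[Indel]:
    if ind.kind == "DEL":
        s, L = ind.ref_start, ind.length
        if s + L < len(ref) and ref[s] == ref[s + L]:
            return replace(ind, ref_start=s + 1)
    else:
        p = ind.ref_start
        if p < len(ref) and ind.inserted_seq[0] == ref[p]:
            return replace(
                ind, ref_start=p + 1, inserted_seq=ind.inserted_seq[1:] + ref[p]
            )
    return None


def _cut_distance(ind: Indel, cut_index: int) -> int:
    lo, hi = ind.interval()
    if ind.kind == "INS":
        return abs(ind.ref_start - cut_index)
    return max(lo - cut_index, cut_index - hi, 0)


def reanchor_indel(ref: str, ind: Indel, cut_index: int) -> Indel:
    """Canonical cut-proximal placement among alignment-equivalent ones.

    Equivalent placements (identical alternative sequence) are enumerated by
    shifting through repeat context; the placement closest to the cut wins,
    leftmost on ties.
    """
    placements = [ind]
    cur = ind
    while (nxt := _shift_left(ref, cur)) is not None and len(placements) < len(ref):
        placements.append(nxt)
        cur = nxt
    cur = ind
    while (nxt := _shift_right(ref, cur)) is not None and len(placements) < 2 * len(ref):
        placements.append(nxt)
        cur = nxt
    return min(placements, key=lambda i: (_cut_distance(i, cut_index), i.ref_start))


def _indels_from_alignment(aln, ref: str, read: str) -> list[Indel]:
    ref_blocks, read_blocks = (
        [(int(a), int(b)) for a, b in block] for block in aln.aligned
    )
    indels: list[Indel] = []
    pr, pq = 0, 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > pr:
            indels.append(Indel("DEL", pr, rs - pr))
        if qs > pq:
            indels.append(Indel("INS", rs, qs - pq, read[pq:qs]))
        pr, pq = re_, qe
    if len(ref) > pr:
        indels.append(Indel("DEL", pr, len(ref) - pr))
    if len(read) > pq:
        indels.append(Indel("INS", len(ref), len(read) - pq, read[pq:]))
    return indels


def align_allele(
    ref: str, read: str, cut_index: Optional[int] = None, read_count: int = 1
) -> Allele:
    """Globally align a read against the reference amplicon and emit its
    indel descriptor list (substitutions are not recorded).

    Scores: match +2, mismatch -1, gap open -5, gap extend -1. Indels are
    left-aligned by the aligner's first optimal path and then, when
    ``cut_index`` is given, re-anchored cut-proximally.
    """
    r = as_seq(ref)
    q = as_seq(read)
    if not r or not q:
        raise ValueError("align_allele requires non-empty sequences")
    if r == q:
        return Allele(indels=(), read_count=read_count, sequence=q)
    aln = _ALIGNER.align(r, q)[0]
    indels = _indels_from_alignment(aln, r, q)
    if cut_index is not None:
        indels = [reanchor_indel(r, i, cut_index) for i in indels]
    return Allele(indels=tuple(indels), read_count=read_count, sequence=q)


# --- classification --------------------------------------------------------


def _overlaps_window(ind: Indel, cut: int, window: int) -> bool:
    lo, hi = ind.interval()
    if ind.kind == "INS":
        return cut - window <= ind.ref_start <= cut + window
    return lo < cut + window and hi > cut - window


def _dsodn_orientation(inserted: str, dsodn: str, k: int) -> Optional[str]:
    if len(inserted) < k or len(dsodn) < k:
        return None
    fwd = {dsodn[i : i + k] for i in range(len(dsodn) - k + 1)}
    rc = revcomp(dsodn)
    rev = {rc[i : i + k] for i in range(len(rc) - k + 1)}
    for i in range(len(inserted) - k + 1):
        sub = inserted[i : i + k]
        if sub in fwd:
            return "FWD"
        if sub in rev:
            return "REV"
    return None


def _is_xx_deletion(ref: str, ind: Indel, cut: int) -> bool:
    """1-nt deletion at the cut of a base identical to the base immediately
    across the cut boundary (G deleting in G|G, C in C|C, ...)."""
    s = ind.ref_start
    if ind.length != 1 or s not in (cut - 1, cut):
        return False
    across = ref[cut] if s == cut - 1 else ref[cut - 1]
    return 0 <= cut - 1 and cut < len(ref) and ref[s] == across


def classify_allele(
    site: TargetSite, allele: Allele, context: ClassifyContext = ClassifyContext()
) -> RepairClass:
    """Assign the allele its repair class (see module docstring cascade).

    Rules 2-9 operate on the indels overlapping the quantification window;
    indels entirely outside the window are ignored as distal noise.
    """
    ref = site.amplicon
    cut = site.cut_index
    for ind in allele.indels:
        lo, hi = ind.interval()
        if not (0 <= lo <= len(ref) and hi <= len(ref)):
            raise ValueError(f"indel {ind} outside the amplicon")
    inds = [reanchor_indel(ref, i, cut) for i in allele.indels]
    inds = [i for i in inds if _overlaps_window(i, cut, context.window)]
    if not inds:
        return RepairClass.UNMODIFIED

    insertions = [i for i in inds if i.kind == "INS"]

    if (
        context.hdr_insert
        and len(inds) == 1
        and insertions
        and insertions[0].ref_start == cut
        and insertions[0].inserted_seq == as_seq(context.hdr_insert)
    ):
        return RepairClass.HDR

    if context.dsodn:
        for ins in insertions:
            orient = _dsodn_orientation(
                ins.inserted_seq, as_seq(context.dsodn), context.dsodn_min_match
            )
            if orient == "FWD":
                return RepairClass.DSODN_FWD
            if orient == "REV":
                return RepairClass.DSODN_REV

    if len(inds) == 1 and insertions:
        ins = insertions[0]
        if ins.length == 1 and ins.ref_start == cut:
            base = ins.inserted_seq
            template = minus4_base(site)
            observed = base if site.strand == "+" else revcomp(base)
            if observed == template:
                return RepairClass.NHEJ_INS1_TEMPLATED
        return RepairClass.NHEJ_INS_OTHER

    if len(inds) == 1 and inds[0].kind == "DEL":
        d = inds[0]
        s, e = d.interval()
        if find_microhomology(ref, s, e, 2, 5) is not None or _is_xx_deletion(ref, d, cut):
            return RepairClass.MMEJ
        if d.length == 1:
            return RepairClass.NHEJ_DEL1
        return RepairClass.NHEJ_DEL_OTHER

    return RepairClass.COMPLEX


@dataclass
class ClassifiedTable:
    """Classification result over an allele table.

    ``relative_frequencies`` divide per-class read counts by the edited read
    total (UNMODIFIED excluded); when no read is edited it is an explicit
    empty mapping, not 0/0.
    """

    per_allele: pd.DataFrame
    class_counts: dict[RepairClass, int]
    total_reads: int
    edited_reads: int
    relative_frequencies: dict[RepairClass, float] = field(default_factory=dict)

    def top_allele_relative_frequencies(self, n: int) -> dict[str, float]:
        """Alternative statistic: each of the ``n`` most frequent edited
        alleles as a fraction of those alleles' combined reads."""
        edited = self.per_allele[self.per_allele["class"] != RepairClass.UNMODIFIED.value]
        top = edited.nlargest(n, "read_count")
        denom = int(top["read_count"].sum())
        if denom == 0:
            return {}
        return {
            str(row.allele_id): row.read_count / denom for row in top.itertuples()
        }


def classify_table(
    site: TargetSite,
    alleles: Iterable[Allele],
    context: ClassifyContext = ClassifyContext(),
) -> ClassifiedTable:
    """Classify every allele and aggregate read counts per repair class."""
    alleles = list(alleles)
    if not alleles:
        raise ValueError("classify_table requires a non-empty allele list")
    rows = []
    counts: dict[RepairClass, int] = {c: 0 for c in RepairClass}
    for k, al in enumerate(alleles):
        cls = classify_allele(site, al, context)
        counts[cls] += al.read_count
        rows.append(
            {
                "allele_id": al.allele_id or f"A{k + 1}",
                "read_count": al.read_count,
                "n_inserted": sum(i.length for i in al.indels if i.kind == "INS"),
                "n_deleted": sum(i.length for i in al.indels if i.kind == "DEL"),
                "indel_descriptor": format_indels(al.indels) or ".",
                "class": cls.value,
            }
        )
    total = sum(counts.values())
    edited = total - counts[RepairClass.UNMODIFIED]
    rel: dict[RepairClass, float] = {}
    per_allele = pd.DataFrame(rows)
    if edited > 0:
        rel = {c: counts[c] / edited for c in EDITED_CLASSES if counts[c] > 0}
        per_allele["relative_frequency"] = [
            (r["read_count"] / edited) if r["class"] != RepairClass.UNMODIFIED.value else float("nan")
            for r in rows
        ]
    else:
        per_allele["relative_frequency"] = float("nan")
    counts = {c: n for c, n in counts.items() if n > 0}
    return ClassifiedTable(
        per_allele=per_allele,
        class_counts=counts,
        total_reads=total,
        edited_reads=edited,
        relative_frequencies=rel,
    )


def indel_frequency(table: ClassifiedTable) -> float:
    """Fraction of reads carrying an edit: edited reads / total reads."""
    if table.total_reads <= 0:
        raise ValueError("indel_frequency requires total reads > 0")
    return table.edited_reads / table.total_reads
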