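"""Editing-target models: protospacer/PAM geometry, dual SpCas9/SaCas9
compatible sites, spacer-length variants, and PAM subtype classification.

Geometry convention: blunt Cas9 cleavage is placed 3 bp 5' of the PAM for
both nucleases, i.e. at the boundary between protospacer positions -4 and
-3 (PAM-relative). The base at position -4 is the one duplicated by fill-in
repair of a 1-nt staggered cut, which is the diagnostic the repair-outcome
classifier is anchored on. Coordinates are 0-based, half-open, plus-strand;
minus-strand sites carry plus-strand coordinates plus a strand flag, and all
reported sequences are protospacer-strand oriented.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqcore
from .seqcore import as_seq, complement_base, iupac_match, revcomp, scan_pam

__all__ = [
    "PAM_PATTERNS",
    "SPACER_RANGES",
    "DUAL_PAM",
    "TargetSite",
    "SpacerVariant",
    "make_site",
    "find_dual_sites",
    "build_spacer",
    "classify_pam",
    "minus4_base",
    "protospacer_seq",
]

PAM_PATTERNS = {"SpCas9": "NGG", "SaCas9": "NNGRRT"}
SPACER_RANGES = {"SpCas9": (18, 21), "SaCas9": (19, 23)}
#: 6-mer satisfied only by sites both nucleases can target (NGG and NNGRRT).
DUAL_PAM = "NGGRRT"
PAM_CLASSES = ("NNGGGT", "NNGAGT", "NNGAAT", "NNGGAT")


@dataclass(frozen=True)
class TargetSite:
    """A protospacer + PAM on an amplicon, with cut geometry.

    ``pam`` is stored as the 6-mer 3' of the protospacer in protospacer-
    strand orientation (SpCas9 checks use its first 3 nt). ``cut_index`` is
    the plus-strand boundary coordinate of the blunt cut (between PAM-
    relative protospacer positions -4 and -3).
    """

    amplicon: str
    strand: str
    protospacer_start: int
    protospacer_end: int
    pam: str
    nuclease: str
    cut_index: int
    name: str = ""


@dataclass(frozen=True)
class SpacerVariant:
    """A guide spacer of a given length; ``five_prime_matched`` records
    whether the obligatory 5' G (required by the U6 promoter) matches the
    genomic base (GN...) or substitutes it (gN...)."""

    length: int
    sequence: str
    five_prime_matched: bool


def make_site(
    amplicon: str,
    strand: str,
    protospacer_start: int,
    protospacer_end: int,
    nuclease: str,
    name: str = "",
) -> TargetSite:
    """Construct and validate a TargetSite from plus-strand protospacer
    coordinates. The PAM 6-mer is read off the amplicon immediately 3' of
    the protospacer on the protospacer strand."""
    amp = as_seq(amplicon)
    if nuclease not in PAM_PATTERNS:
        raise ValueError(f"unknown nuclease {nuclease!r}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    s, e = protospacer_start, protospacer_end
    if not (0 <= s < e <= len(amp)):
        raise ValueError("protospacer interval out of amplicon range")
    if strand == "+":
        if e + 6 > len(amp):
            raise ValueError("PAM extends past the amplicon 3' edge")
        pam = amp[e : e + 6]
        cut = e - 3
    else:
        if s - 6 < 0:
            raise ValueError("PAM extends past the amplicon 5' edge")
        pam = revcomp(amp[s - 6 : s])
        cut = s + 3
    pattern = PAM_PATTERNS[nuclease]
    probe = pam[: len(pattern)]
    if not iupac_match(probe, pattern):
        raise ValueError(f"PAM {pam!r} does not match {pattern} for {nuclease}")
    return TargetSite(amp, strand, s, e, pam, nuclease, cut, name)


def protospacer_seq(site: TargetSite) -> str:
    """Protospacer sequence in protospacer-strand orientation."""
    window = site.amplicon[site.protospacer_start : site.protospacer_end]
    return window if site.strand == "+" else revcomp(window)


def find_dual_sites(
    amplicon: str, protospacer_len: int = 20
) -> list[tuple[TargetSite, TargetSite]]:
    """All dual-compatible target sites on an amplicon.

    Every NGGRRT 6-mer (both strands) yields a paired SpCas9 site (NGG = its
    first 3 nt) and SaCas9 site (the full 6-mer) sharing the protospacer
    3' end. Hits without room for a full protospacer are skipped.
    """
    amp = as_seq(amplicon)
    if len(amp) < 30:
        raise ValueError("amplicon too short for dual-site search (< 30 nt)")
    pairs = []
    for pos, strand in scan_pam(amp, DUAL_PAM, both_strands=True):
        if strand == "+":
            s, e = pos - protospacer_len, pos
            if s < 0:
                continue
        else:
            s, e = pos + 6, pos + 6 + protospacer_len
            if e > len(amp):
                continue
        sp = make_site(amp, strand, s, e, "SpCas9")
        sa = make_site(amp, strand, s, e, "SaCas9")
        pairs.append((sp, sa))
    return pairs


def build_spacer(site: TargetSite, length: int) -> SpacerVariant:
    """Spacer of the requested length for a site: the ``length`` 3'-most
    protospacer-strand bases, with the 5' base forced to G (matched G kept,
    anything else substituted by a mismatched g)."""
    if not (18 <= length <= 23):
        raise ValueError(f"spacer length {length} outside the supported 18-23 nt range")
    lo, hi = SPACER_RANGES[site.nuclease]
    if not (lo <= length <= hi):
        raise ValueError(
            f"spacer length {length} outside the {site.nuclease} range {lo}-{hi} nt"
        )
    if site.strand == "+":
        s, e = site.protospacer_end - length, site.protospacer_end
        if s < 0:
            raise ValueError("spacer extends past the amplicon 5' edge")
        genomic = site.amplicon[s:e]
    else:
        s, e = site.protospacer_start, site.protospacer_start + length
        if e > len(site.amplicon):
            raise ValueError("spacer extends past the amplicon edge")
        genomic = revcomp(site.amplicon[s:e])
    matched = genomic[0] == "G"
    seq = genomic if matched else "G" + genomic[1:]
    return SpacerVariant(length=length, sequence=seq, five_prime_matched=matched)


def classify_pam(site_or_pam: TargetSite | str) -> str:
    """PAM subtype of an SaCas9 site, determined by the RR dinucleotide of
    the NNGRRT frame: one of NNGGGT / NNGAGT / NNGAAT / NNGGAT."""
    pam = site_or_pam.pam if isinstance(site_or_pam, TargetSite) else as_seq(site_or_pam)
    if len(pam) != 6 or not iupac_match(pam, "NNGRRT"):
        raise ValueError(f"PAM {pam!r} does not match NNGRRT")
    return f"NNG{pam[3]}{pam[4]}T"


def minus4_base(site: TargetSite) -> str:
    """Protospacer-strand base at PAM-relative position -4 (immediately 5'
    of the cut): the base duplicated by templated +1 NHEJ after a 1-nt
    staggered cut."""
    if site.strand == "+":
        return site.amplicon[site.protospacer_end - 4]
    return complement_base(site.amplicon[site.protospacer_start + 3])
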