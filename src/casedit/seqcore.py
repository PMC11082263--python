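"""Deterministic sequence primitives shared by every pipeline stage.

All coordinates are 0-based, half-open, on the plus strand. Sequences are
plain ``str`` over A/C/G/T/N; lowercase input is accepted and upcased.
IUPAC degenerate symbols (the 15-letter nucleotide code) are supported for
patterns such as PAM motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "IUPAC",
    "as_seq",
    "revcomp",
    "complement_base",
    "iupac_match",
    "scan_pam",
    "pam_density",
    "hamming",
    "strip_modifications",
    "anneal",
    "DuplexReport",
    "MicrohomologyCall",
    "find_microhomology",
]

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_SEQ_ALPHABET = frozenset("ACGTN")


def as_seq(s: str) -> str:
    """Normalize a nucleotide sequence: upcase and validate A/C/G/T/N."""
    t = s.upper()
    bad = set(t) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return t


def complement_base(b: str) -> str:
    return b.upper().translate(_COMPLEMENT)


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement (IUPAC-aware; N maps to N)."""
    t = s.upper()
    bad = set(t) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return t.translate(_COMPLEMENT)[::-1]


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff every base of ``seq`` is in the base set of the paired
    ``pattern`` symbol. Lengths must agree."""
    s = as_seq(seq)
    p = pattern.upper()
    if len(s) != len(p):
        raise ValueError(f"length mismatch: seq {len(s)} vs pattern {len(p)}")
    try:
        return all(b in IUPAC[sym] for b, sym in zip(s, p))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc} in pattern {p!r}") from exc


def _iupac_regex(pattern: str) -> str:
    parts = []
    for sym in pattern.upper():
        if sym not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in pattern {pattern!r}")
        bases = "".join(sorted(IUPAC[sym]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_pam(
    genome: str, pattern: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All occurrences of an IUPAC ``pattern`` in ``genome``.

    Overlapping hits are all counted. Minus-strand hits are reported at the
    plus-strand coordinate of the match window (0-based start). Returns a
    coordinate-sorted list of ``(start, strand)``.
    """
    g = as_seq(genome)
    L = len(pattern)
    if L == 0 or len(g) < L:
        raise ValueError("genome shorter than pattern")
    # Lookahead regex so overlapping occurrences are all found.
    rx = re.compile(f"(?={_iupac_regex(pattern)})")
    hits = [(m.start(), "+") for m in rx.finditer(g)]
    if both_strands:
        n = len(g)
        hits.extend((n - m.start() - L, "-") for m in rx.finditer(revcomp(g)))
    hits.sort()
    return hits


def pam_density(pattern: str) -> float:
    """Expected genomic spacing (bp per occurrence, both strands) of an
    IUPAC motif under i.i.d. uniform base composition.

    Closed form ``1 / (2 * prod_i |baseset_i| / 4)``: the per-position match
    probability on one strand, doubled for the two strands, inverted.
    """
    p = 1.0
    for sym in pattern.upper():
        if sym not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in pattern {pattern!r}")
        p *= len(IUPAC[sym]) / 4.0
    return 1.0 / (2.0 * p)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def strip_modifications(oligo: str) -> str:
    """Reduce a printed oligo (with 5'-P labels, phosphorothioate ``*``
    marks, and punctuation) to its bare nucleotide sequence.

    Chemistry annotations are not sequence: every character that is not a
    nucleotide letter is discarded (the leading ``P`` of a 5'-phosphate
    label is punctuation-delimited and therefore also dropped explicitly).
    """
    s = oligo.upper()
    # Drop an explicit phosphate label before filtering letters.
    s = re.sub(r"\bP\b", "", s)
    s = s.replace("5'", "").replace("3'", "").replace("5′", "").replace("3′", "")
    return "".join(c for c in s if c in "ACGTN")


@dataclass(frozen=True)
class DuplexReport:
    """Outcome of annealing two ssODNs: duplex length, whether the duplex is
    blunt (perfect reverse-complement), and the number of mispaired bases."""

    length: int
    blunt: bool
    mismatches: Optional[int]


def anneal(o1: str, o2: str) -> DuplexReport:
    """Anneal two single-stranded oligos and report the duplex.

    ``blunt`` is true iff ``o2`` is exactly the reverse complement of ``o1``.
    For equal-length oligos the mismatch count pairs o1 with revcomp(o2)
    position by position; for unequal lengths no per-position pairing is
    defined and ``mismatches`` is None.
    """
    a = as_seq(o1)
    b = as_seq(o2)
    if not a or not b:
        raise ValueError("anneal requires two non-empty oligos")
    blunt = b == revcomp(a)
    mism = hamming(a, revcomp(b)) if len(a) == len(b) else None
    return DuplexReport(length=max(len(a), len(b)), blunt=blunt, mismatches=mism)


@dataclass(frozen=True)
class MicrohomologyCall:
    """A pair of identical substrings flanking a deletion.

    ``left_start``/``right_start`` are the 0-based plus-strand coordinates of
    the two homologous copies; in the left-side form the right copy is the
    3' end of the deleted interval, in the right-side form the left copy is
    the 5' end of the deleted interval.
    """

    length: int
    left_start: int
    right_start: int


def find_microhomology(
    ref: str, del_start: int, del_end: int, min_len: int = 2, max_len: int = 5
) -> Optional[MicrohomologyCall]:
    """Longest flanking repeat of length ``min_len..max_len`` consistent
    with microhomology-mediated repair of the deletion ``[del_start, del_end)``.

    Two symmetric forms are checked for each length k (longest first, left
    form preferred on ties):

    * left form:  ``ref[del_start-k:del_start] == ref[del_end-k:del_end]``
      (one repeat copy immediately 5' of the deletion, the other forming the
      3' end of the deleted interval);
    * right form: ``ref[del_start:del_start+k] == ref[del_end:del_end+k]``.

    Returns None when no length qualifies.
    """
    n = len(ref)
    if not (0 <= del_start < del_end <= n):
        raise ValueError(f"deletion [{del_start},{del_end}) out of range for ref of length {n}")
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    for k in range(max_len, min_len - 1, -1):
        if (
            del_start - k >= 0
            and del_end - k >= del_start
            and ref[del_start - k : del_start] == ref[del_end - k : del_end]
        ):
            return MicrohomologyCall(k, del_start - k, del_end - k)
        if (
            del_end + k <= n
            and del_start + k <= del_end
            and ref[del_start : del_start + k] == ref[del_end : del_end + k]
        ):
            return MicrohomologyCall(k, del_start, del_end)
    return None
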