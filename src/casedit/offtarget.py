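"""GUIDE-seq-lite off-target stage.

Junction reads carrying the 34-bp dsODN tag are located, their genomic
flanks exact-matched to a (synthetic, desk-scale) genome, integration
positions single-linkage clustered into sites, protospacer-length windows
matched around each site by Hamming distance (up to 6 protospacer
mismatches; the PAM is recorded but not used as a filter), and the
off-index statistic computed: total off-target reads divided by on-target
reads, a scale-free per-guide specificity measure.

Read counts are raw junction-read counts (no UMI consolidation); this is a
deliberate divergence from full-scale GUIDE-seq, matched to the simulator,
which emits reads rather than molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .seqcore import as_seq, hamming, revcomp

__all__ = [
    "JunctionRead",
    "RawSite",
    "OffTargetSite",
    "ProtospacerMatch",
    "OffIndexResult",
    "extract_junctions",
    "map_and_cluster",
    "match_protospacer",
    "identify_sites",
    "off_index",
    "render_report",
]


@dataclass(frozen=True)
class JunctionRead:
    """A read containing the dsODN tag: the longer genomic flank, the tag
    orientation in the read, and which side of the tag the flank came from
    ('L' = flank 5' of the tag in the read)."""

    flank: str
    orientation: str  # "FWD" | "REV"
    flank_side: str  # "L" | "R"


@dataclass(frozen=True)
class RawSite:
    """A cluster of integration positions before protospacer matching."""

    chrom: str
    position: int  # minimum junction coordinate in the cluster
    read_count: int


@dataclass(frozen=True)
class ProtospacerMatch:
    sequence: str
    strand: str
    start: int
    mismatch_count: int
    mismatch_string: str
    pam_seq: str


@dataclass(frozen=True)
class OffTargetSite:
    chrom: str
    position: int
    strand: str
    read_count: int
    matched_protospacer: str
    pam_seq: str
    mismatch_count: int
    mismatch_string: str
    is_on_target: bool


@dataclass(frozen=True)
class OffIndexResult:
    on_reads: int
    off_reads_total: int
    off_index: float


def _best_tag_hit(read: str, probe: str, max_mm: int) -> Optional[tuple[int, int]]:
    """Best (position, mismatches) of ``probe`` within ``read``, or None."""
    n, L = len(read), len(probe)
    if n < L:
        return None
    # Exact fast path covers the overwhelmingly common error-free case.
    pos = read.find(probe)
    if pos >= 0:
        return (pos, 0)
    if max_mm == 0:
        return None
    best: Optional[tuple[int, int]] = None
    for i in range(n - L + 1):
        mm = 0
        window = read[i : i + L]
        for a, b in zip(window, probe):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            if best is None or mm < best[1]:
                best = (i, mm)
    return best


def extract_junctions(
    reads: Iterable[str], dsodn: str, max_mm: int = 2, min_flank: int = 25
) -> list[JunctionRead]:
    """Reads containing the dsODN tag (either orientation, <= ``max_mm``
    mismatches) yield their longer genomic flank; other reads are dropped,
    as are reads whose flank is shorter than ``min_flank``."""
    tag = as_seq(dsodn)
    tag_rc = revcomp(tag)
    out = []
    for read in reads:
        r = as_seq(read)
        fwd = _best_tag_hit(r, tag, max_mm)
        rev = _best_tag_hit(r, tag_rc, max_mm)
        if fwd is None and rev is None:
            continue
        if rev is None or (fwd is not None and fwd[1] <= rev[1]):
            pos, orientation = fwd[0], "FWD"
        else:
            pos, orientation = rev[0], "REV"
        left = r[:pos]
        right = r[pos + len(tag) :]
        flank, side = (left, "L") if len(left) >= len(right) else (right, "R")
        if len(flank) < min_flank:
            continue
        out.append(JunctionRead(flank=flank, orientation=orientation, flank_side=side))
    return out


def _map_flank(
    junction: JunctionRead, genome: Mapping[str, str]
) -> Optional[tuple[str, int]]:
    """Exact-match a flank on both strands; return the junction coordinate
    (the flank end that abutted the dsODN) or None for unmapped /
    multi-mapping flanks."""
    flank = junction.flank
    rc = revcomp(flank)
    hits: list[tuple[str, int, str]] = []
    for chrom, seq in genome.items():
        for probe, strand in ((flank, "+"), (rc, "-")):
            start = seq.find(probe)
            while start >= 0:
                hits.append((chrom, start, strand))
                if len(hits) > 1:
                    return None  # ambiguous multi-mapper
                start = seq.find(probe, start + 1)
    if not hits:
        return None
    chrom, start, strand = hits[0]
    L = len(flank)
    if junction.flank_side == "L":
        pos = start + L if strand == "+" else start
    else:
        pos = start if strand == "+" else start + L
    return (chrom, pos)


def map_and_cluster(
    junctions: Iterable[JunctionRead],
    genome: Mapping[str, str],
    cluster_window: int = 25,
) -> list[RawSite]:
    """Map junction flanks and merge integration positions within
    ``cluster_window`` of each other (single linkage, per chromosome).
    The cluster representative is the minimum coordinate."""
    positions: dict[str, list[int]] = {}
    for j in junctions:
        hit = _map_flank(j, genome)
        if hit is None:
            continue
        positions.setdefault(hit[0], []).append(hit[1])
    sites = []
    for chrom in sorted(positions):
        pos = sorted(positions[chrom])
        start = 0
        for k in range(1, len(pos) + 1):
            if k == len(pos) or pos[k] - pos[k - 1] > cluster_window:
                sites.append(RawSite(chrom, pos[start], k - start))
                start = k
    return sites


def match_protospacer(
    genome_seq: str,
    site_pos: int,
    spacer: str,
    pam_pattern: Optional[str] = None,
    search_radius: int = 25,
    max_mm: int = 6,
) -> Optional[ProtospacerMatch]:
    """Best (fewest-mismatch) protospacer-length window within
    ``search_radius`` of ``site_pos`` on either strand.

    Hamming distance is computed over protospacer positions only; the
    adjacent PAM-frame sequence is recorded for display but never used as a
    filter. Returns None when the best window exceeds ``max_mm``
    mismatches. Ties break by proximity to ``site_pos``, then plus strand,
    then leftmost.
    """
    g = as_seq(genome_seq)
    sp = as_seq(spacer)
    L = len(sp)
    lo = max(0, site_pos - search_radius - L)
    hi = min(len(g) - L, site_pos + search_radius)
    best: Optional[tuple[tuple[int, int, int], ProtospacerMatch]] = None
    for start in range(lo, hi + 1):
        window = g[start : start + L]
        for strand in "+-":
            cand = window if strand == "+" else revcomp(window)
            mm = hamming(sp, cand)
            if mm > max_mm:
                continue
            dist = max(start - site_pos, site_pos - (start + L), 0)
            key = (mm, dist, 0 if strand == "+" else 1)
            if best is not None and (key, start) >= (best[0], best[1].start):
                continue
            mm_string = "".join(
                "." if a == b else b for a, b in zip(sp, cand)
            )
            if strand == "+":
                pam = g[start + L : start + L + 6]
            else:
                pam = revcomp(g[max(0, start - 6) : start])
            pam = pam.ljust(6, "N")
            best = (
                key,
                ProtospacerMatch(cand, strand, start, mm, mm_string, pam),
            )
    return best[1] if best else None


def identify_sites(
    genome: Mapping[str, str],
    reads: Iterable[str],
    spacer: str,
    dsodn: str,
    max_mm: int = 6,
    tag_max_mm: int = 2,
    cluster_window: int = 25,
    search_radius: int = 25,
    on_target: Optional[tuple[str, int]] = None,
) -> list[OffTargetSite]:
    """End-to-end site calling: junctions -> clusters -> protospacer match.

    Clusters without a protospacer match within ``max_mm`` mismatches are
    not reported. The on-target site is the one whose matched window
    overlaps the declared ``(chrom, position)`` when given; otherwise the
    perfect-match (0-mismatch) site. Among several candidates the highest
    read count wins (position breaks remaining ties) so exactly one site
    carries the flag.
    """
    junctions = extract_junctions(reads, dsodn, max_mm=tag_max_mm)
    raw = map_and_cluster(junctions, genome, cluster_window=cluster_window)
    matched: list[tuple[RawSite, ProtospacerMatch]] = []
    for site in raw:
        m = match_protospacer(
            genome[site.chrom],
            site.position,
            spacer,
            search_radius=search_radius,
            max_mm=max_mm,
        )
        if m is not None:
            matched.append((site, m))

    def _is_on(site: RawSite, m: ProtospacerMatch) -> bool:
        if on_target is not None:
            chrom, pos = on_target
            return site.chrom == chrom and m.start <= pos <= m.start + len(spacer)
        return m.mismatch_count == 0

    candidates = [i for i, (s, m) in enumerate(matched) if _is_on(s, m)]
    on_idx = None
    if candidates:
        on_idx = max(
            candidates, key=lambda i: (matched[i][0].read_count, -matched[i][0].position)
        )
    out = []
    for i, (site, m) in enumerate(matched):
        out.append(
            OffTargetSite(
                chrom=site.chrom,
                position=site.position,
                strand=m.strand,
                read_count=site.read_count,
                matched_protospacer=m.sequence,
                pam_seq=m.pam_seq,
                mismatch_count=m.mismatch_count,
                mismatch_string=m.mismatch_string,
                is_on_target=(i == on_idx),
            )
        )
    return out


def off_index(sites: Sequence[OffTargetSite]) -> OffIndexResult:
    """Total off-target reads divided by on-target reads."""
    on = [s for s in sites if s.is_on_target]
    if len(on) != 1:
        raise ValueError(f"expected exactly one on-target site, found {len(on)}")
    on_reads = on[0].read_count
    if on_reads <= 0:
        raise ValueError("on-target read count must be > 0")
    off_total = sum(s.read_count for s in sites if not s.is_on_target)
    return OffIndexResult(on_reads, off_total, off_total / on_reads)


def render_report(sites: Sequence[OffTargetSite], spacer: str) -> str:
    """Text rendering of matched sites with matching bases as dots."""
    lines = [f"target  {as_seq(spacer)}  PAM     reads  mm"]
    ordered = sorted(sites, key=lambda s: (not s.is_on_target, -s.read_count))
    for s in ordered:
        tag = "on " if s.is_on_target else "off"
        lines.append(
            f"{tag}     {s.mismatch_string}  {s.pam_seq}  {s.read_count:>6}  {s.mismatch_count}"
        )
    return "\n".join(lines)
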