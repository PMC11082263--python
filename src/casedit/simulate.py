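"""Synthetic-data generators for every pipeline input.

Three families of generators, all bit-reproducible under (seed, parameters):

* repair-outcome allele tables under nuclease-specific multinomial
  profiles, rendered as concrete cut-anchored indel descriptors that the
  classifier maps back to the drawn outcome (closed loop);
* error-bearing amplicon reads expanded from an allele table;
* synthetic genomes with protospacer-like windows planted at exact Hamming
  distances plus dsODN junction reads for the off-target stage.

The demo target site carries an engineered core around the cut: the -4
base is A (so templated +1 repair inserts +A), the bases across the cut are
A|A (the single-base X|X MMEJ case), and 2-5 nt repeats are planted on the
two sides of the cut so that microhomology-mediated deletions of every
length class exist. Flanks are seeded random sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .classify import (
    Allele,
    ClassifyContext,
    Indel,
    RepairClass,
    classify_allele,
    apply_indels,
    format_indels,
)
from .seqcore import as_seq, hamming, revcomp
from .site_model import TargetSite, make_site, minus4_base, protospacer_seq

__all__ = [
    "DSODN",
    "HDR_INSERT",
    "RepairProfile",
    "load_profiles",
    "load_guideseq_scenarios",
    "make_demo_site",
    "simulate_alleles",
    "render_reads",
    "PlantedSite",
    "PlantedGenome",
    "plant_offtargets",
    "simulate_guideseq_reads",
]

#: The 34-nt top strand of the blunt GUIDE-seq bait duplex (chemical marks
#: stripped; its partner oligo is the exact reverse complement).
DSODN = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"
#: Default 6-bp donor insert used for NGS-detectable HDR knock-in.
HDR_INSERT = "GGATCC"

OUTCOMES = (
    "ins1_templated",
    "ins1_random",
    "del1_nhej",
    "mmej",
    "del_other",
    "hdr",
    "dsodn",
)

_INTENDED_CLASS = {
    "ins1_templated": {RepairClass.NHEJ_INS1_TEMPLATED},
    "ins1_random": {RepairClass.NHEJ_INS_OTHER},
    "del1_nhej": {RepairClass.NHEJ_DEL1},
    "mmej": {RepairClass.MMEJ},
    "del_other": {RepairClass.NHEJ_DEL_OTHER},
    "hdr": {RepairClass.HDR},
    "dsodn": {RepairClass.DSODN_FWD, RepairClass.DSODN_REV},
}


@dataclass(frozen=True)
class RepairProfile:
    """Outcome probabilities driving the allele simulator.

    ``conditional`` probabilities are conditional on the read being edited
    and must sum to 1; ``mh_length_weights`` spread MMEJ deletions over
    flanking-repeat lengths 1 (X|X) to 5 nt; other-deletion lengths follow
    a geometric distribution (mean ``del_other_mean``) truncated at
    ``del_other_max``.
    """

    label: str
    p_unmodified: float
    conditional: dict[str, float]
    mh_length_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.3, 3: 0.2, 4: 0.15, 5: 0.15}
    )
    del_other_mean: float = 8.0
    del_other_max: int = 30
    p_dsodn_forward: float = 0.5

    def validate(self) -> None:
        if not (0.0 <= self.p_unmodified <= 1.0):
            raise ValueError("p_unmodified must be in [0, 1]")
        unknown = set(self.conditional) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome keys: {sorted(unknown)}")
        vals = [self.conditional.get(k, 0.0) for k in OUTCOMES]
        if any(v < 0 for v in vals):
            raise ValueError("outcome probabilities must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"conditional probabilities sum to {sum(vals)}, not 1")
        if not self.mh_length_weights or any(
            k not in (1, 2, 3, 4, 5) or w < 0 for k, w in self.mh_length_weights.items()
        ):
            raise ValueError("mh_length_weights must map lengths 1-5 to weights >= 0")


def _profiles_from_yaml(name: str) -> dict:
    path = resources.files("casedit").joinpath("profiles", name)
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def load_profiles(path: Optional[str] = None) -> dict[str, RepairProfile]:
    """Packaged (or user-supplied YAML) repair profiles by name."""
    if path is None:
        raw = _profiles_from_yaml("default_profiles.yaml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    out = {}
    for name, cfg in raw.items():
        prof = RepairProfile(
            label=cfg.get("label", name),
            p_unmodified=float(cfg["p_unmodified"]),
            conditional={k: float(v) for k, v in cfg["conditional"].items()},
            mh_length_weights={int(k): float(v) for k, v in cfg.get(
                "mh_length_weights", {1: 0.2, 2: 0.3, 3: 0.2, 4: 0.15, 5: 0.15}
            ).items()},
            del_other_mean=float(cfg.get("del_other_mean", 8)),
            del_other_max=int(cfg.get("del_other_max", 30)),
        )
        prof.validate()
        out[name] = prof
    return out


def load_guideseq_scenarios(path: Optional[str] = None) -> dict[str, dict]:
    """Packaged (or user-supplied) on/off-target read-weight scenarios."""
    if path is None:
        return _profiles_from_yaml("guideseq_scenarios.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


# --- demo target -----------------------------------------------------------

# Protospacer with the engineered core (see module docstring): -4 base A,
# A|A across the cut, and left microhomology copies at fixed offsets.
_DEMO_PROTOSPACER = "GCATTCGAGCCTAGCCAACG"
_DEMO_PAM = "TGGAGT"  # NGG prefix + NNGRRT frame: dual-compatible
# Copies of the protospacer-internal repeats replanted 3' of the PAM so that
# deletions spanning the cut leave a 2-5 nt flanking repeat:
#   TAG (3), GC (2), CCTA (4), AGCCT (5) = protospacer slices [11:14],
#   [13:15], [9:13], [7:12].
_DEMO_DOWNSTREAM_CORE = "TAGGCCCTAAGCCT"


def make_demo_site(
    nuclease: str = "SpCas9", seed: int = 0, flank_len: int = 60, name: str = "demo"
) -> TargetSite:
    """A dual-compatible demonstration target on a synthetic amplicon."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, size=flank_len))
    right = "".join(rng.choice(bases, size=flank_len))
    amplicon = left + _DEMO_PROTOSPACER + _DEMO_PAM + _DEMO_DOWNSTREAM_CORE + right
    start = flank_len
    end = flank_len + len(_DEMO_PROTOSPACER)
    return make_site(amplicon, "+", start, end, nuclease, name=name)


# --- allele simulation -----------------------------------------------------


def _mmej_catalog(site: TargetSite, ctx: ClassifyContext) -> dict[int, Indel]:
    """For each flanking-repeat length 1-5, one deletion near the cut that
    the classifier calls MMEJ; planted-structure lookup by bounded scan."""
    ref = site.amplicon
    cut = site.cut_index
    catalog: dict[int, Indel] = {}
    # X|X single-base case.
    if 0 < cut < len(ref) and ref[cut - 1] == ref[cut]:
        ind = Indel("DEL", cut, 1)
        if classify_allele(site, Allele((ind,), 1), ctx) is RepairClass.MMEJ:
            catalog[1] = ind
    for k in (2, 3, 4, 5):
        found = None
        for s in range(max(k, cut - ctx.window), cut + 1):
            for e in range(s + k, min(len(ref) - k + 1, s + site_max_del(site))):
                if ref[s - k : s] == ref[e - k : e]:
                    ind = Indel("DEL", s, e - s)
                    if classify_allele(site, Allele((ind,), 1), ctx) is RepairClass.MMEJ:
                        found = ind
                        break
            if found:
                break
        if found:
            catalog[k] = found
    return catalog


def site_max_del(site: TargetSite) -> int:
    """Longest deletion the simulator will attempt on this amplicon."""
    return min(30, len(site.amplicon) - site.cut_index - 1, site.cut_index - 1) + 1


def _render_del1(site: TargetSite, ctx: ClassifyContext) -> Indel:
    cut = site.cut_index
    for off in (0, -1, 1, -2, 2, -3, 3):
        s = cut + off
        if not (0 <= s < len(site.amplicon)):
            continue
        ind = Indel("DEL", s, 1)
        if classify_allele(site, Allele((ind,), 1), ctx) is RepairClass.NHEJ_DEL1:
            return ind
    raise RuntimeError("no 1-nt deletion near the cut classifies as NHEJ -1 on this site")


def _draw_del_other(
    site: TargetSite, ctx: ClassifyContext, rng: np.random.Generator, profile: RepairProfile
) -> Indel:
    ref = site.amplicon
    cut = site.cut_index
    for _ in range(200):
        d = int(rng.geometric(1.0 / profile.del_other_mean))
        if d < 2 or d > profile.del_other_max:
            continue
        offset = int(rng.integers(-(d - 1), 1))  # interval touches the cut
        s = cut + offset
        if s < 1 or s + d > len(ref) - 1:
            continue
        ind = Indel("DEL", s, d)
        if classify_allele(site, Allele((ind,), 1), ctx) is RepairClass.NHEJ_DEL_OTHER:
            return ind
    raise RuntimeError("could not render a plain deletion free of microhomology")


def simulate_alleles(
    site: TargetSite,
    profile: RepairProfile,
    n_reads: int,
    seed: int,
    hdr_insert: str = HDR_INSERT,
    dsodn: str = DSODN,
    window: int = 10,
) -> list[Allele]:
    """Draw ``n_reads`` repair outcomes from the profile and render each as
    a concrete indel descriptor consistent with its class.

    Every rendered descriptor is verified against the classifier (with the
    same HDR/dsODN context) before emission, so the generator's class
    labels and the classifier's calls agree by construction on an
    error-free path. Deterministic under ``seed``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    profile.validate()
    rng = np.random.default_rng(seed)
    ctx = ClassifyContext(hdr_insert=hdr_insert, dsodn=dsodn, window=window)
    pu = profile.p_unmodified
    probs = [pu] + [(1 - pu) * profile.conditional.get(k, 0.0) for k in OUTCOMES]
    counts = rng.multinomial(n_reads, probs)
    tally: dict[tuple[Indel, ...], int] = {}

    def _emit(indels: tuple[Indel, ...], n: int, outcome: Optional[str]) -> None:
        if n <= 0:
            return
        if outcome is not None:
            got = classify_allele(site, Allele(indels, 1), ctx)
            if got not in _INTENDED_CLASS[outcome]:
                raise RuntimeError(
                    f"rendered {outcome} allele classifies as {got.value} on this site"
                )
        tally[indels] = tally.get(indels, 0) + n

    cut = site.cut_index
    _emit((), counts[0], None)  # unmodified

    n_by = dict(zip(OUTCOMES, counts[1:]))

    if n_by["ins1_templated"]:
        base = minus4_base(site)
        plus_base = base if site.strand == "+" else revcomp(base)
        _emit((Indel("INS", cut, 1, plus_base),), n_by["ins1_templated"], "ins1_templated")

    if n_by["ins1_random"]:
        template = minus4_base(site)
        plus_template = template if site.strand == "+" else revcomp(template)
        others = [b for b in "ACGT" if b != plus_template]
        split = rng.multinomial(n_by["ins1_random"], [1 / 3] * 3)
        for b, n in zip(others, split):
            _emit((Indel("INS", cut, 1, b),), int(n), "ins1_random")

    if n_by["del1_nhej"]:
        _emit((_render_del1(site, ctx),), n_by["del1_nhej"], "del1_nhej")

    if n_by["mmej"]:
        catalog = _mmej_catalog(site, ctx)
        if not catalog:
            raise RuntimeError("no microhomology-compatible deletion exists on this site")
        lengths = sorted(catalog)
        weights = np.array(
            [profile.mh_length_weights.get(k, 0.0) for k in lengths], dtype=float
        )
        if weights.sum() == 0:
            weights = np.ones(len(lengths))
        split = rng.multinomial(n_by["mmej"], weights / weights.sum())
        for k, n in zip(lengths, split):
            _emit((catalog[k],), int(n), "mmej")

    for _ in range(n_by["del_other"]):
        _emit((_draw_del_other(site, ctx, rng, profile),), 1, "del_other")

    if n_by["hdr"]:
        _emit((Indel("INS", cut, len(hdr_insert), as_seq(hdr_insert)),), n_by["hdr"], "hdr")

    if n_by["dsodn"]:
        tag = as_seq(dsodn)
        n_fwd = int(rng.binomial(n_by["dsodn"], profile.p_dsodn_forward))
        _emit((Indel("INS", cut, len(tag), tag),), n_fwd, "dsodn")
        _emit((Indel("INS", cut, len(tag), revcomp(tag)),), n_by["dsodn"] - n_fwd, "dsodn")

    alleles = []
    for k, (indels, n) in enumerate(
        sorted(tally.items(), key=lambda kv: format_indels(kv[0]))
    ):
        alleles.append(Allele(indels=indels, read_count=n, allele_id=f"A{k + 1}"))
    return alleles


def render_reads(
    site: TargetSite,
    alleles: Sequence[Allele],
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Expand an allele table into (id, sequence, quality) read tuples with
    i.i.d. substitution errors at ``error_rate``; qualities are constant."""
    if not (0.0 <= error_rate < 0.05):
        raise ValueError("error_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    reads = []
    n = 0
    for al in alleles:
        seq = apply_indels(site.amplicon, al.indels)
        for _ in range(al.read_count):
            n += 1
            if error_rate > 0:
                arr = list(seq)
                hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
                for i in hits:
                    arr[i] = bases[(bases.index(arr[i]) + int(rng.integers(1, 4))) % 4]
                out = "".join(arr)
            else:
                out = seq
            reads.append((f"read{n}_{al.allele_id or 'A'}", out, "I" * len(out)))
    return reads


# --- planted genomes and junction reads ------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """One planted protospacer-like window: plus-strand window start, cut
    coordinate, strand, exact Hamming distance to the spacer, and the mean
    junction-read weight used by the read simulator."""

    position: int
    cut: int
    strand: str
    mismatches: int
    weight: float


@dataclass(frozen=True)
class PlantedGenome:
    name: str
    genome: str
    spacer: str
    pam_pattern: str
    sites: tuple[PlantedSite, ...]

    @property
    def on_target(self) -> PlantedSite:
        return next(s for s in self.sites if s.mismatches == 0)


def _concrete_pam(pattern: str, rng: np.random.Generator) -> str:
    from .seqcore import IUPAC

    return "".join(sorted(IUPAC[sym])[int(rng.integers(len(IUPAC[sym])))] for sym in pattern)


def _mutate(spacer: str, d: int, rng: np.random.Generator) -> str:
    arr = list(spacer)
    pos = rng.choice(len(arr), size=d, replace=False)
    for i in pos:
        arr[i] = "ACGT".replace(arr[i], "")[int(rng.integers(3))]
    return "".join(arr)


def plant_offtargets(
    spacer: str,
    pam_pattern: str = "NNGRRT",
    mismatch_counts: Sequence[int] = (0,),
    weights: Optional[Sequence[float]] = None,
    genome_len: int = 100_000,
    seed: int = 0,
    min_separation: int = 400,
    search_radius: int = 25,
    max_tries: int = 200,
) -> PlantedGenome:
    """Seeded random genome with spacer-like windows planted at exact
    Hamming distances (plus a matching PAM frame 3' of each window).

    The on-target window (0 mismatches) is always planted (prepended when
    absent from ``mismatch_counts``). Each placement is verified post hoc:
    the planted window's Hamming distance must be exactly as requested and
    no window within ``search_radius`` of its cut may beat it; violations
    trigger a re-draw, bounded by ``max_tries``.
    """
    sp = as_seq(spacer)
    L = len(sp)
    mm = list(mismatch_counts)
    if 0 not in mm:
        mm = [0] + mm
    else:
        mm = [0] + [d for i, d in enumerate(mm) if d != 0 or i != mm.index(0)]
    if any(d < 0 or d > L for d in mm):
        raise ValueError("mismatch counts must be within 0..len(spacer)")
    if weights is None:
        weights = [100.0] * len(mm)
    if len(weights) != len(mm):
        raise ValueError("weights must align with mismatch_counts (on-target first)")
    rng = np.random.default_rng(seed)
    genome = list("ACGT"[i] for i in rng.integers(0, 4, size=genome_len))
    span = L + 12  # window + PAM head-room on either side
    if (min_separation + span) * len(mm) > genome_len:
        raise ValueError("genome too small for the requested number of sites")

    def _best_nearby(g: str, cut: int, ignore: tuple[int, int]) -> int:
        best = L + 1
        for s in range(max(0, cut - search_radius - L), min(len(g) - L, cut + search_radius) + 1):
            if ignore[0] == s:
                continue
            w = g[s : s + L]
            best = min(best, hamming(sp, w), hamming(sp, revcomp(w)))
        return best

    sites: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    for d, w in zip(mm, weights):
        for attempt in range(max_tries):
            p = int(rng.integers(span, genome_len - span))
            if any(abs(p - q) < min_separation for q, _ in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            window = _mutate(sp, d, rng) if d else sp
            pam = _concrete_pam(pam_pattern, rng)
            g = genome.copy()
            if strand == "+":
                g[p : p + L] = list(window)
                g[p + L : p + L + len(pam)] = list(pam)
                cut = p + L - 3
            else:
                g[p : p + L] = list(revcomp(window))
                g[p - len(pam) : p] = list(revcomp(pam))
                cut = p + 3
            gs = "".join(g)
            # Post-hoc oracle: exact planted distance, and nothing nearby
            # (other than the planted window itself) scores better.
            planted = gs[p : p + L] if strand == "+" else revcomp(gs[p : p + L])
            if hamming(planted, sp) != d:
                continue
            if _best_nearby(gs, cut, (p, p + L)) < d:
                continue
            genome = g
            sites.append(PlantedSite(p, cut, strand, d, float(w)))
            occupied.append((p, p + L))
            break
        else:
            raise RuntimeError(
                f"failed to place a {d}-mismatch site after {max_tries} tries"
            )
    return PlantedGenome(
        name="synth1",
        genome="".join(genome),
        spacer=sp,
        pam_pattern=pam_pattern,
        sites=tuple(sites),
    )


def simulate_guideseq_reads(
    planted: PlantedGenome,
    dsodn: str = DSODN,
    seed: int = 0,
    flank_len: int = 30,
    reads_per_site: Optional[Sequence[float]] = None,
) -> list[str]:
    """Poisson(weight) junction reads per planted site: the plus-strand
    genomic flank 5' of the cut followed by the dsODN tag in random
    orientation."""
    if flank_len < 25:
        raise ValueError("flank_len must be >= 25 so flanks are mappable")
    tag = as_seq(dsodn)
    rng = np.random.default_rng(seed)
    weights = (
        [s.weight for s in planted.sites] if reads_per_site is None else list(reads_per_site)
    )
    reads = []
    for site, w in zip(planted.sites, weights):
        n = int(rng.poisson(w))
        flank = planted.genome[site.cut - flank_len : site.cut]
        for _ in range(n):
            fwd = rng.random() < 0.5
            reads.append(flank + (tag if fwd else revcomp(tag)))
    return reads
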