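"""GUIDE-seq-lite stage: junction extraction, mapping/clustering,
bounded-mismatch protospacer matching, and the off-index statistic."""

import numpy as np
import pytest

from casedit import offtarget as ot
from casedit import seqcore as sq
from casedit import simulate as sim

DSODN = sim.DSODN
SPACER = "GCATTCGAGCCTAGCCAACG"


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# --- extract_junctions -----------------------------------------------------


def test_extract_junction_forward():
    flank = _random_seq(1, 30)
    [j] = ot.extract_junctions([flank + DSODN], DSODN)
    assert j.orientation == "FWD" and j.flank == flank and j.flank_side == "L"


def test_extract_junction_reverse():
    flank = _random_seq(2, 30)
    [j] = ot.extract_junctions([flank + sq.revcomp(DSODN)], DSODN)
    assert j.orientation == "REV" and j.flank == flank


def test_extract_junction_right_flank():
    flank = _random_seq(3, 30)
    [j] = ot.extract_junctions([DSODN + flank], DSODN)
    assert j.flank == flank and j.flank_side == "R"


def test_extract_junction_mismatch_threshold():
    flank = _random_seq(4, 30)
    tag = list(DSODN)
    for i in (3, 11, 20):  # three substitutions
        tag[i] = "ACGT".replace(tag[i], "")[0]
    assert ot.extract_junctions([flank + "".join(tag)], DSODN, max_mm=2) == []
    assert len(ot.extract_junctions([flank + "".join(tag)], DSODN, max_mm=3)) == 1


def test_extract_junction_drops_reads_without_tag():
    assert ot.extract_junctions([_random_seq(5, 80)], DSODN) == []


# --- map_and_cluster -------------------------------------------------------


def _junctions_at(genome, positions, flank_len=30):
    reads = [genome[p - flank_len : p] + DSODN for p in positions]
    return ot.extract_junctions(reads, DSODN)


def test_map_single_locus():
    genome = _random_seq(6, 3000)
    sites = ot.map_and_cluster(_junctions_at(genome, [500] * 10), {"chr": genome})
    assert len(sites) == 1
    assert sites[0].position == 500 and sites[0].read_count == 10


def test_two_distant_loci_stay_separate():
    genome = _random_seq(7, 3000)
    sites = ot.map_and_cluster(_junctions_at(genome, [500, 1500]), {"chr": genome}, 25)
    assert [(s.position, s.read_count) for s in sites] == [(500, 1), (1500, 1)]


def test_single_linkage_clustering_by_hand():
    # positions {100, 110, 160}, window 25 -> clusters {100,110} and {160}
    genome = _random_seq(8, 2000)
    sites = ot.map_and_cluster(_junctions_at(genome, [100, 110, 160]), {"chr": genome}, 25)
    assert [(s.position, s.read_count) for s in sites] == [(100, 2), (160, 1)]


def test_multimapping_flank_dropped():
    genome = _random_seq(9, 1000)
    dup = genome[100:130]
    genome = genome + dup + _random_seq(10, 100)  # flank now occurs twice
    reads = [genome[100:130] + DSODN]
    assert ot.map_and_cluster(ot.extract_junctions(reads, DSODN), {"chr": genome}) == []


# --- match_protospacer -----------------------------------------------------


def brute_best_match(genome, site_pos, spacer, radius, max_mm):
    """Independent full scan over every window and strand in the radius."""
    L = len(spacer)
    best = None
    for start in range(max(0, site_pos - radius - L), min(len(genome) - L, site_pos + radius) + 1):
        w = genome[start : start + L]
        for strand, cand in (("+", w), ("-", sq.revcomp(w))):
            mm = sq.hamming(spacer, cand)
            dist = max(start - site_pos, site_pos - (start + L), 0)
            key = (mm, dist, 0 if strand == "+" else 1, start)
            if best is None or key < best:
                best = key
    return best if best and best[0] <= max_mm else None


def _genome_with_planted(seed, subs=()):
    rng = np.random.default_rng(seed)
    g = list(_random_seq(seed, 2000))
    window = list(SPACER)
    for i in subs:
        window[i] = "ACGT".replace(window[i], "")[int(rng.integers(3))]
    g[1000 : 1000 + len(SPACER)] = window
    return "".join(g)


def test_perfect_protospacer_match():
    g = _genome_with_planted(20)
    m = ot.match_protospacer(g, 1017, SPACER)
    assert m.mismatch_count == 0 and m.start == 1000 and m.strand == "+"
    assert m.mismatch_string == "." * len(SPACER)


def test_three_substitutions_marked():
    g = _genome_with_planted(21, subs=(2, 9, 15))
    m = ot.match_protospacer(g, 1017, SPACER)
    assert m.mismatch_count == 3
    marked = [i for i, ch in enumerate(m.mismatch_string) if ch != "."]
    assert marked == [2, 9, 15]


def test_seven_mismatches_not_reported():
    g = _genome_with_planted(22, subs=(0, 3, 6, 9, 12, 15, 18))
    m = ot.match_protospacer(g, 1017, SPACER, max_mm=6)
    # nothing within 6 mismatches near the planted window (random background
    # sits far above the threshold)
    assert m is None
    assert ot.match_protospacer(g, 1017, SPACER, max_mm=7).mismatch_count == 7


@pytest.mark.parametrize("seed", range(8))
def test_match_agrees_with_brute_force(seed):
    subs = tuple(np.random.default_rng(seed).choice(20, size=seed % 5, replace=False))
    g = _genome_with_planted(seed + 50, subs=subs)
    pos = int(np.random.default_rng(seed + 99).integers(990, 1030))
    m = ot.match_protospacer(g, pos, SPACER)
    b = brute_best_match(g, pos, SPACER, 25, 6)
    if b is None:
        assert m is None
    else:
        assert (m.mismatch_count, m.start) == (b[0], b[3])


# --- off_index -------------------------------------------------------------


def _site(reads, on=False, pos=0, mm=0):
    return ot.OffTargetSite(
        "chr", pos, "+", reads, SPACER, "TGGAGT", mm, "." * 20, on
    )


def test_off_index_arithmetic():
    sites = [_site(1000, on=True), _site(50, pos=500, mm=3), _site(50, pos=900, mm=4)]
    r = ot.off_index(sites)
    assert (r.on_reads, r.off_reads_total) == (1000, 100)
    assert r.off_index == pytest.approx(0.1)


def test_off_index_no_offtargets_is_zero():
    assert ot.off_index([_site(1000, on=True)]).off_index == 0.0


def test_off_index_scale_invariance():
    a = [_site(1000, on=True), _site(50, pos=500), _site(50, pos=900)]
    b = [_site(7000, on=True), _site(350, pos=500), _site(350, pos=900)]
    assert ot.off_index(a).off_index == pytest.approx(ot.off_index(b).off_index)


def test_off_index_requires_single_on_target():
    with pytest.raises(ValueError):
        ot.off_index([_site(10, pos=5), _site(10, pos=900)])
    with pytest.raises(ValueError):
        ot.off_index([_site(10, on=True), _site(10, on=True, pos=900)])


# --- end to end ------------------------------------------------------------


def test_end_to_end_planted_mismatch_threshold():
    """Sites planted at Hamming distances 0..8: everything within 6
    mismatches is reported, everything beyond is absent."""
    pg = sim.plant_offtargets(
        SPACER, mismatch_counts=list(range(9)), weights=[40.0] * 9, seed=3
    )
    reads = sim.simulate_guideseq_reads(pg, seed=4)
    sites = ot.identify_sites(
        {pg.name: pg.genome}, reads, SPACER, DSODN, on_target=(pg.name, pg.on_target.cut)
    )
    reported = sorted(s.mismatch_count for s in sites)
    assert reported == [0, 1, 2, 3, 4, 5, 6]
    assert sum(s.is_on_target for s in sites) == 1
    on = next(s for s in sites if s.is_on_target)
    assert on.mismatch_count == 0


def test_render_report_shows_dots(demo_site):
    sites = [_site(1000, on=True), _site(50, pos=500, mm=0)]
    text = ot.render_report(sites, SPACER)
    assert SPACER in text and "." * 20 in text
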