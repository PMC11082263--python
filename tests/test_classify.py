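"""Repair-outcome classification: the decision cascade, alignment-derived
indel descriptors, cut-proximal re-anchoring, and table aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casedit import classify as cl
from casedit import seqcore as sq
from casedit import simulate as sim
from casedit.classify import Allele, ClassifyContext, Indel, RepairClass
from casedit.site_model import make_site, minus4_base

CTX = ClassifyContext(hdr_insert=sim.HDR_INSERT, dsodn=sim.DSODN, window=10)


def one(site, *indels):
    return cl.classify_allele(site, Allele(tuple(indels), 1), CTX)


# --- decision cascade ------------------------------------------------------


def test_unmodified_without_indels(demo_site):
    assert one(demo_site) is RepairClass.UNMODIFIED


def test_distal_indel_is_unmodified(demo_site):
    ind = Indel("DEL", demo_site.cut_index - 40, 3)
    assert one(demo_site, ind) is RepairClass.UNMODIFIED


def test_templated_plus_one_insertion(demo_site):
    c = demo_site.cut_index
    assert minus4_base(demo_site) == "A"
    assert one(demo_site, Indel("INS", c, 1, "A")) is RepairClass.NHEJ_INS1_TEMPLATED


def test_non_templated_single_insertion(demo_site):
    c = demo_site.cut_index
    assert one(demo_site, Indel("INS", c, 1, "T")) is RepairClass.NHEJ_INS_OTHER
    assert one(demo_site, Indel("INS", c, 2, "AA")) is RepairClass.NHEJ_INS_OTHER


def test_xx_single_base_deletion_is_mmej(demo_site):
    # the demo locus has A|A across the cut
    c = demo_site.cut_index
    assert demo_site.amplicon[c - 1] == demo_site.amplicon[c] == "A"
    assert one(demo_site, Indel("DEL", c, 1)) is RepairClass.MMEJ


def test_tg_style_deletion_is_nhej_minus1():
    # deleting G in a T|G context: the across-cut base differs, so this is
    # a -1 NHEJ event, not the X|X microhomology case
    amplicon = "T" * 20 + "GTCGGATCAAGTCAGGTGAC" + "CGGAGT" + "ACGTACGTACGTACGTACGT"
    site = make_site(amplicon, "+", 20, 40, "SpCas9")
    c = site.cut_index
    assert site.amplicon[c - 1] == "T" and site.amplicon[c] == "G"
    assert cl.classify_allele(
        site, Allele((Indel("DEL", c, 1),), 1), ClassifyContext(window=10)
    ) is RepairClass.NHEJ_DEL1


def test_microhomology_deletion_is_mmej(demo_site):
    """Deletion spanning the cut with a planted 2-nt flanking repeat; the
    independent microhomology oracle confirms the repeat."""
    c = demo_site.cut_index
    ind = Indel("DEL", c - 2, 16)
    s, e = ind.interval()
    assert sq.find_microhomology(demo_site.amplicon, s, e, 2, 5) is not None
    assert one(demo_site, ind) is RepairClass.MMEJ


def test_plain_deletion_is_nhej_del_other(demo_site):
    c = demo_site.cut_index
    ind = Indel("DEL", c - 1, 5)
    if sq.find_microhomology(demo_site.amplicon, c - 1, c + 4, 2, 5) is None:
        assert one(demo_site, ind) is RepairClass.NHEJ_DEL_OTHER


def test_hdr_exact_insert(demo_site):
    c = demo_site.cut_index
    assert one(demo_site, Indel("INS", c, 6, sim.HDR_INSERT)) is RepairClass.HDR


def test_hdr_requires_exact_insert(demo_site):
    c = demo_site.cut_index
    wrong = "GGATCT"
    assert one(demo_site, Indel("INS", c, 6, wrong)) is RepairClass.NHEJ_INS_OTHER


def test_dsodn_orientations(demo_site):
    c = demo_site.cut_index
    tag = sim.DSODN
    assert one(demo_site, Indel("INS", c, 34, tag)) is RepairClass.DSODN_FWD
    assert one(demo_site, Indel("INS", c, 34, sq.revcomp(tag))) is RepairClass.DSODN_REV
    # junction-trimmed integration still detected via a 20-nt exact substring
    trimmed = tag[5:30]
    assert one(demo_site, Indel("INS", c, len(trimmed), trimmed)) is RepairClass.DSODN_FWD


def test_short_dsodn_fragment_not_called(demo_site):
    c = demo_site.cut_index
    frag = sim.DSODN[:15]
    assert one(demo_site, Indel("INS", c, len(frag), frag)) is RepairClass.NHEJ_INS_OTHER


def test_multiple_indels_are_complex(demo_site):
    c = demo_site.cut_index
    assert (
        one(demo_site, Indel("DEL", c - 4, 2), Indel("INS", c + 3, 1, "T"))
        is RepairClass.COMPLEX
    )


def test_templated_call_is_strand_invariant(demo_site):
    """The same physical +1 event classifies identically whether the locus
    is encoded on the plus or the minus strand."""
    amp = demo_site.amplicon
    n = len(amp)
    flipped = sq.revcomp(amp)
    site_minus = make_site(
        flipped,
        "-",
        n - demo_site.protospacer_end,
        n - demo_site.protospacer_start,
        "SpCas9",
    )
    assert site_minus.cut_index == n - demo_site.cut_index
    base = minus4_base(demo_site)
    assert minus4_base(site_minus) == base
    ins = Indel("INS", site_minus.cut_index, 1, sq.revcomp(base))
    got = cl.classify_allele(site_minus, Allele((ins,), 1), CTX)
    assert got is RepairClass.NHEJ_INS1_TEMPLATED


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_classification_is_total_and_exclusive(seed):
    """Every random allele receives exactly one class without error."""
    site = sim.make_demo_site("SpCas9", seed=0)
    rng = np.random.default_rng(seed)
    n = len(site.amplicon)
    indels = []
    pos = 5
    for _ in range(int(rng.integers(0, 3))):
        pos = int(rng.integers(pos, n - 12))
        if rng.random() < 0.5:
            length = int(rng.integers(1, 8))
            indels.append(Indel("DEL", pos, min(length, n - pos - 1)))
            pos += length + 1
        else:
            length = int(rng.integers(1, 5))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
            indels.append(Indel("INS", pos, length, seq))
            pos += 1
        if pos >= n - 12:
            break
    got = cl.classify_allele(site, Allele(tuple(indels), 1), CTX)
    assert got in RepairClass


# --- alignment -------------------------------------------------------------


def test_align_identical_read_has_no_indels(demo_site):
    al = cl.align_allele(demo_site.amplicon, demo_site.amplicon)
    assert al.indels == ()


def test_align_recovers_planted_deletion(demo_site):
    ref = demo_site.amplicon
    planted = Indel("DEL", demo_site.cut_index - 2, 4)
    read = cl.apply_indels(ref, [planted])
    al = cl.align_allele(ref, read, cut_index=demo_site.cut_index)
    assert len(al.indels) == 1
    got = al.indels[0]
    assert got.kind == "DEL" and got.length == 4
    # any alignment-equivalent placement renders the same read
    assert cl.apply_indels(ref, al.indels) == read


def test_homopolymer_deletion_reanchored_cut_proximally():
    ref = "TTTTCAAAAGTTTTTTTTTT"
    cut = 9  # boundary right of the A-run
    read = ref[:5] + ref[6:]  # delete one A (leftmost placement)
    al = cl.align_allele(ref, read, cut_index=cut)
    assert len(al.indels) == 1
    ind = al.indels[0]
    assert (ind.kind, ind.length) == ("DEL", 1)
    # cut-proximal equivalent placement: the A adjacent to the boundary
    assert ind.ref_start == 8
    assert cl.apply_indels(ref, al.indels) == read


def test_equivalent_placements_classify_identically(demo_site):
    """A deletion inside a repeat yields the same class wherever the
    aligner first puts it."""
    ref = demo_site.amplicon
    c = demo_site.cut_index
    ind = Indel("DEL", c, 1)  # A of the A|A pair; equivalent to [c-1, c)
    a = cl.classify_allele(demo_site, Allele((ind,), 1), CTX)
    b = cl.classify_allele(demo_site, Allele((Indel("DEL", c - 1, 1),), 1), CTX)
    assert a is b is RepairClass.MMEJ


# --- table aggregation -----------------------------------------------------


def _counted_alleles(demo_site, counts):
    c = demo_site.cut_index
    by_class = {
        "TEMPLATED": Indel("INS", c, 1, "A"),
        "MMEJ": Indel("DEL", c - 2, 16),
        "DEL1": Indel("DEL", c + 1, 1),
    }
    alleles = []
    for name, n in counts.items():
        if name == "UNMODIFIED":
            alleles.append(Allele((), n, allele_id="wt"))
        else:
            alleles.append(Allele((by_class[name],), n, allele_id=name))
    return alleles


def test_classify_table_relative_frequencies(demo_site):
    table = cl.classify_table(
        demo_site, _counted_alleles(demo_site, {"TEMPLATED": 70, "MMEJ": 20, "DEL1": 10}), CTX
    )
    rel = table.relative_frequencies
    assert rel[RepairClass.NHEJ_INS1_TEMPLATED] == pytest.approx(0.70)
    assert rel[RepairClass.MMEJ] == pytest.approx(0.20)
    assert rel[RepairClass.NHEJ_DEL1] == pytest.approx(0.10)
    assert sum(rel.values()) == pytest.approx(1.0, abs=1e-9)


def test_unmodified_reads_do_not_change_relative_frequencies(demo_site):
    counts = {"TEMPLATED": 70, "MMEJ": 20, "DEL1": 10}
    t1 = cl.classify_table(demo_site, _counted_alleles(demo_site, counts), CTX)
    t2 = cl.classify_table(
        demo_site, _counted_alleles(demo_site, {**counts, "UNMODIFIED": 900}), CTX
    )
    assert t1.relative_frequencies == t2.relative_frequencies
    assert t2.total_reads == 1000 and t2.edited_reads == 100


def test_all_unmodified_yields_explicit_empty_result(demo_site):
    table = cl.classify_table(demo_site, [Allele((), 500, allele_id="wt")], CTX)
    assert table.edited_reads == 0
    assert table.relative_frequencies == {}
    assert cl.indel_frequency(table) == 0.0


def test_indel_frequency(demo_site):
    table = cl.classify_table(
        demo_site,
        _counted_alleles(demo_site, {"TEMPLATED": 100, "UNMODIFIED": 900}),
        CTX,
    )
    assert cl.indel_frequency(table) == pytest.approx(0.10)


def test_round_trip_simulate_render_align_classify(demo_site, profiles):
    """simulate -> render error-free reads -> align -> classify recovers the
    generator's class for >= 99% of alleles."""
    alleles = sim.simulate_alleles(demo_site, profiles["spcas9_like"], 1500, seed=7)
    direct = {
        al.allele_id: cl.classify_allele(demo_site, al, CTX) for al in alleles
    }
    mismatched = total = 0
    for al in alleles:
        seq = cl.apply_indels(demo_site.amplicon, al.indels)
        realigned = cl.align_allele(demo_site.amplicon, seq, cut_index=demo_site.cut_index)
        got = cl.classify_allele(demo_site, realigned, CTX)
        total += al.read_count
        if got is not direct[al.allele_id]:
            mismatched += al.read_count
    assert mismatched / total <= 0.01
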