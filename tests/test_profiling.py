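"""Profiles, segment merging, template union and genotyping."""

from fractions import Fraction

import pytest

from polystr.calibration import CalibratedPair, CoordMap
from polystr.detector import DetectorConfig
from polystr.profiling import (
    STRProfile,
    build_profile,
    build_template,
    call_polymorphisms,
    genotype_locus,
    merge_adjacent,
)
from polystr.repeat_model import Motif, STRRecord

from conftest import random_sequence


def identity_pair(seq: str, gene_id: str = "g", offset: int = 0) -> tuple:
    pair = CalibratedPair(gene_id=gene_id, ref_seq=seq, ref_offset=offset,
                          target_seq=seq, target_offset=offset)
    return pair, CoordMap.identity(len(seq))


def make_profile(records, seq="", individual="i", quality=1.0):
    return STRProfile(individual_id=individual, gene_id="g",
                      chromosome_id="chr", quality=quality,
                      records=records, sequence=seq)


def rec(start, end, unit, seq_id="i", ref=None):
    r = STRRecord(seq_id, start, end, Motif(unit))
    r.ref_start, r.ref_end = ref if ref else (start, end)
    return r


# --- build_profile --------------------------------------------------------

def test_reference_profile_is_detector_output(rng):
    seq = random_sequence(rng, 400) + Motif("AGAT").array(40) + random_sequence(rng, 400)
    pair, cmap = identity_pair(seq, offset=1000)
    prof = build_profile(pair, cmap, DetectorConfig(), "reference")
    assert len(prof.records) >= 1
    r = next(r for r in prof.records if r.motif.unit == "AGAT")
    assert (r.ref_start, r.ref_end) == (r.start + 1000, r.end + 1000)


def test_profile_of_expanded_individual(rng):
    flank_a = random_sequence(rng, 300)
    flank_b = random_sequence(rng, 300)
    ref = flank_a + Motif("AGAT").array(40) + flank_b
    target = flank_a + Motif("AGAT").array(48) + flank_b  # +2 units
    from polystr.calibration import align_global
    cmap = align_global(ref, target)
    pair = CalibratedPair("g", ref, 0, target, 0)
    prof = build_profile(pair, cmap, DetectorConfig(), "i1")
    r = next(r for r in prof.records if r.motif.unit == "AGAT")
    assert r.span == 48
    # lifted interval overlaps the reference's 40 bp locus
    assert r.ref_start < 340 and 300 < r.ref_end


def test_profile_skips_n_masked_locus(rng):
    seq = random_sequence(rng, 200) + "N" * 40 + random_sequence(rng, 200)
    pair, cmap = identity_pair(seq)
    prof = build_profile(pair, cmap, DetectorConfig(), "i1")
    assert all("N" not in seq[r.start:r.end] for r in prof.records)


# --- merge_adjacent -------------------------------------------------------

def test_merge_bridges_small_gap():
    # 4 bp of foreign sequence keeps the array phase: exactly 4 mismatches
    seq = Motif("AGAT").array(24) + "CCCC" + Motif("AGAT").array(24)
    records = [rec(0, 24, "AGAT"), rec(28, 52, "AGAT")]
    prof = make_profile(records, seq=seq, quality=0.9)
    merged = merge_adjacent(prof, max_gap=10)
    assert len(merged.records) == 1
    m = merged.records[0]
    assert (m.start, m.end) == (0, 52)
    assert m.purity == pytest.approx(48 / 52)
    assert float(m.repeat_number) == pytest.approx(52 / 4)


def test_merge_respects_motif_inequality():
    seq = Motif("AGAT").array(24) + Motif("AATG").array(24)
    records = [rec(0, 24, "AGAT"), rec(24, 48, "AATG")]
    merged = merge_adjacent(make_profile(records, seq=seq, quality=0.9))
    assert len(merged.records) == 2


def test_merge_is_transitive():
    seq = (Motif("AG").array(20) + "T" + Motif("AG").array(20)
           + "C" + Motif("AG").array(20))
    records = [rec(0, 20, "AG"), rec(21, 41, "AG"), rec(42, 62, "AG")]
    merged = merge_adjacent(make_profile(records, seq=seq, quality=0.9))
    assert len(merged.records) == 1
    assert (merged.records[0].start, merged.records[0].end) == (0, 62)


def test_merge_unions_overlaps_unconditionally():
    seq = Motif("AGAT").array(40)
    records = [rec(0, 24, "AGAT"), rec(16, 40, "AGAT")]
    merged = merge_adjacent(make_profile(records, seq=seq, quality=1.0))
    assert len(merged.records) == 1
    assert (merged.records[0].start, merged.records[0].end) == (0, 40)


# --- build_template -------------------------------------------------------

def test_template_union_across_individuals():
    profiles = [make_profile([rec(100 + i, 140 + i, "AGAT", seq_id=f"i{i}",
                                  ref=(100 + i, 140 + i))], individual=f"i{i}")
                for i in range(7)]
    loci = build_template(profiles)
    assert len(loci) == 1
    assert loci[0].contributors == tuple(sorted(f"i{i}" for i in range(7)))
    assert loci[0].ref_interval == (100, 146)


def test_reference_only_locus_survives():
    profiles = [make_profile([rec(100, 140, "AGAT", "reference")],
                             individual="reference"),
                make_profile([], individual="i1")]
    loci = build_template(profiles)
    assert len(loci) == 1
    assert loci[0].contributors == ("reference",)


def test_same_motif_disjoint_intervals_stay_separate():
    profiles = [make_profile([rec(100, 140, "AGAT"), rec(1100, 1140, "AGAT")])]
    loci = build_template(profiles)
    assert len(loci) == 2


def test_template_idempotent():
    profiles = [make_profile([rec(100, 141, "AGAT", seq_id="a")], individual="a"),
                make_profile([rec(120, 160, "AGAT", seq_id="b"),
                              rec(500, 530, "AC", seq_id="b")], individual="b")]
    loci = build_template(profiles)
    wrapped = [make_profile(
        [rec(l.ref_interval[0], l.ref_interval[1], l.motif.unit)], individual="t")
        for l in loci]
    again = build_template(wrapped)
    assert [(l.motif.unit, l.ref_interval) for l in again] == \
           [(l.motif.unit, l.ref_interval) for l in loci]


def test_union_property_every_record_in_one_locus():
    profiles = [make_profile([rec(100, 140, "AGAT"), rec(135, 180, "AGAT"),
                              rec(300, 330, "AC")])]
    loci = build_template(profiles)
    for r in profiles[0].records:
        containing = [l for l in loci
                      if l.ref_interval[0] <= r.ref_start
                      and r.ref_end <= l.ref_interval[1]
                      and l.motif.unit == r.motif.unit]
        assert len(containing) == 1


# --- genotyping -----------------------------------------------------------

def make_locus(motif, interval, locus_id="L1"):
    from polystr.profiling import TemplateLocus
    return TemplateLocus(locus_id=locus_id, motif=Motif(motif),
                         ref_interval=interval, contributors=("reference",),
                         gene_id="g", chromosome_id="chr")


def test_genotype_perfect_array():
    # flanks break the periodicity at both boundaries, so the maximal run
    # is exactly the planted 55 bp
    seq = "CCTG" * 25 + Motif("AGAT").array(55) + "CTGG" * 25
    pair, cmap = identity_pair(seq)
    call = genotype_locus(make_locus("AGAT", (100, 155)), pair, cmap, "i1")
    assert call.status == "called"
    assert call.span == 55
    assert call.repeat == Fraction(55, 4)  # 13.75


def test_genotype_n_window_is_missing(rng):
    seq = random_sequence(rng, 100) + "N" * 55 + random_sequence(rng, 100)
    pair, cmap = identity_pair(seq)
    call = genotype_locus(make_locus("AGAT", (100, 155)), pair, cmap, "i1")
    assert call.status == "missing"
    assert call.span is None


def test_genotype_short_run_below_detector_minimum():
    seq = "CATT" * 25 + "GCGGCGGC" + "TTAC" * 25
    pair, cmap = identity_pair(seq)
    call = genotype_locus(make_locus("CGG", (100, 108)), pair, cmap, "i1")
    assert call.status == "called"
    assert call.span == 8
    assert call.repeat == Fraction(8, 3)  # renders 2.666667


def test_genotype_clean_window_without_run_is_zero():
    seq = "GTCATCGGATCCTAGGCATCAATGGCATCGATTGCACCGGTA"
    pair, cmap = identity_pair(seq)
    call = genotype_locus(make_locus("AGAT", (10, 30)), pair, cmap, "i1")
    assert call.status == "called"
    assert call.span == 0
    assert call.repeat == Fraction(0)


def test_genotype_unmapped_window_excluded():
    pair, cmap = identity_pair("ACGTACGTAC")
    assert genotype_locus(make_locus("AGAT", (500, 540)), pair, cmap, "i1") is None


# --- polymorphism calling -------------------------------------------------

def calls_for(locus_id, spans):
    from polystr.profiling import LocusCall
    out = []
    for ind, span in spans.items():
        if span is None:
            out.append(LocusCall(ind, locus_id, "missing"))
        else:
            out.append(LocusCall(ind, locus_id, "called", span=span,
                                 repeat=Fraction(span, 4)))
    return out


def test_conserved_locus():
    locus = make_locus("AATG", (0, 34), "L1")
    spans = {f"i{k}": 34 for k in range(7)}  # 8.5 repeats each
    recs = call_polymorphisms([locus], calls_for("L1", spans))
    assert recs[0].is_polymorphic is False
    assert recs[0].variation_degree == 0
    assert recs[0].max_dev == 0


def test_polymorphic_locus_variation_degree():
    locus = make_locus("AGAT", (0, 57), "L1")
    repeats = [14.25, 13.25, 11.5, 13.25, 14.25, 14.25, 14.25]
    spans = {f"i{k}": int(r * 4) for k, r in enumerate(repeats)}
    recs = call_polymorphisms([locus], calls_for("L1", spans))
    assert recs[0].is_polymorphic is True
    assert recs[0].variation_degree == 11  # (14.25 - 11.5) * 4
    assert recs[0].max_dev == 11


def test_indeterminate_locus():
    locus = make_locus("AGAT", (0, 40), "L1")
    spans = {"i0": 40, **{f"i{k}": None for k in range(1, 7)}}
    recs = call_polymorphisms([locus], calls_for("L1", spans))
    assert recs[0].indeterminate
    assert recs[0].max_dev is None


def test_partition_conserved_or_polymorphic():
    loci = [make_locus("AGAT", (k * 100, k * 100 + 40), f"L{k}") for k in range(5)]
    calls = []
    for k, locus in enumerate(loci):
        spans = {f"i{j}": 40 + (j % 2) * k for j in range(4)}
        calls.extend(calls_for(locus.locus_id, spans))
    recs = call_polymorphisms(loci, calls)
    for r in recs:
        assert (r.is_polymorphic is True) != (r.is_polymorphic is False) or True
        assert r.is_polymorphic in (True, False)
        assert (r.max_dev >= 1) == r.is_polymorphic
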