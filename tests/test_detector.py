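"""Detector contracts: perfect/tolerant runs, purity, and oracle equivalence."""

import numpy as np
import pytest

from polystr.detector import (
    DetectorConfig,
    DetectorConfigError,
    detect_perfect,
    detect_tolerant,
    measure_motif_run,
    purity,
)
from polystr.repeat_model import Motif, canonical_motif

from conftest import random_sequence


# --- independent brute-force oracle -------------------------------------

def oracle_perfect(seq: str, unit_lengths=(1, 2, 3, 4, 5, 6), min_span: int = 20):
    """Maximal perfect runs by direct per-position extension.

    Independent of the vectorized implementation: walks every start
    position for every unit, extends while the periodicity comparison
    holds, keeps maximal runs, then drops runs nested inside a run of a
    divisor unit. Returns a set of (start, end, canonical_unit).
    """
    seq = seq.upper()
    n = len(seq)
    runs = set()
    for u in unit_lengths:
        i = 0
        while i + u < n:
            if seq[i] == "N" or seq[i] != seq[i + u]:
                i += 1
                continue
            # i begins a periodicity run; find its maximal extent
            j = i
            while j + u < n and seq[j + u] != "N" and seq[j] == seq[j + u]:
                j += 1
            start, end = i, j + u
            if end - start >= min_span:
                runs.add((start, end, u))
            i = j + 1
    kept = set()
    for start, end, u in runs:
        nested = any(
            d < u and u % d == 0 and s2 <= start and end <= e2
            for s2, e2, d in runs)
        if not nested:
            kept.add((start, end, canonical_motif(seq[start : start + u]).unit))
    return kept


def oracle_tolerant_intervals(seq: str, motif: Motif, quality: float, min_span: int):
    """All sub-intervals meeting both thresholds, reduced to maximal ones."""
    qualifying = []
    n = len(seq)
    for i in range(n):
        for j in range(i + min_span, n + 1):
            if purity(seq[i:j], motif) >= quality:
                qualifying.append((i, j))
    return [iv for iv in qualifying
            if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                       for o in qualifying)]


def as_set(records):
    return {(r.start, r.end, r.motif.unit) for r in records}


# --- perfect detection ----------------------------------------------------

def test_homopolymer_in_flanks():
    seq = "GTCGTACGTC" + "A" * 25 + "CGTACGGTTC"
    recs = detect_perfect(seq)
    assert len(recs) == 1
    rec = recs[0]
    assert (rec.start, rec.end) == (10, 35)
    assert rec.motif.unit == "A"
    assert float(rec.repeat_number) == 25.0
    assert rec.purity == 1.0


def test_exactly_min_span():
    seq = "TTGCCGGTAC" + "ACAG" * 5 + "TCCTTGGAAC"
    recs = detect_perfect(seq)
    assert len(recs) == 1
    assert recs[0].span == 20
    assert float(recs[0].repeat_number) == 5.0
    assert recs[0].motif.unit == "ACAG"


def test_empty_sequence():
    assert detect_perfect("") == []


def test_perfect_matches_oracle_on_random_sequences(rng):
    for _ in range(30):
        n = int(rng.integers(1000, 2001))
        seq = random_sequence(rng, n)
        # plant a few runs so the comparison is not vacuous
        for _ in range(3):
            m = Motif("ACG") if rng.integers(2) else Motif("AT")
            pos = int(rng.integers(0, n - 60))
            seq = seq[:pos] + m.array(int(rng.integers(20, 45))) + seq[pos + 40:]
        got = as_set(detect_perfect(seq[:n]))
        assert got == oracle_perfect(seq[:n])


def test_perfect_sorted_and_never_overlaps_n(rng):
    seq = random_sequence(rng, 500) + "A" * 30 + "N" * 5 + "A" * 30 + random_sequence(rng, 100)
    recs = detect_perfect(seq)
    starts = [r.start for r in recs]
    assert starts == sorted(starts)
    for r in recs:
        assert "N" not in seq[r.start : r.end]
    # the two A-runs flanking the N block are reported separately
    a_runs = [r for r in recs if r.motif.unit == "A" and r.span >= 30]
    assert len(a_runs) == 2


# --- purity ---------------------------------------------------------------

@pytest.mark.parametrize("region, unit, expected", [
    ("AGATAGAT", "AGAT", 1.0),
    ("AGATCGAT", "AGAT", 0.875),   # one substitution in 8 bp
    ("GATAGATA", "AGAT", 1.0),     # phase-shifted perfect array
])
def test_purity(region, unit, expected):
    assert purity(region, Motif(canonical_motif(unit).unit)) == pytest.approx(expected)


def test_purity_empty_region():
    with pytest.raises(ValueError):
        purity("", Motif("A"))


# --- tolerant detection ---------------------------------------------------

FLANK_L = "GTCCGATCGG TTGACCGTAC".replace(" ", "")
FLANK_R = "CCGGTTAACG GTTGCATGCC".replace(" ", "")


def test_tolerant_bridges_single_substitution():
    # a 49 bp array with position 24 substituted: two perfect 24 bp halves
    arr = list(Motif("AGAT").array(49))
    assert arr[24] == "A"
    arr[24] = "C"
    run = "".join(arr)
    seq = FLANK_L + run + FLANK_R
    recs = detect_tolerant(seq, DetectorConfig(quality=0.9))
    agat = [r for r in recs if r.motif.unit == "AGAT"]
    assert len(agat) == 1
    assert agat[0].span == 49
    assert agat[0].purity == pytest.approx(48 / 49)


def test_quality_one_splits_at_substitution():
    arr = list(Motif("AGAT").array(49))
    arr[24] = "C"
    run = "".join(arr)
    seq = FLANK_L + run + FLANK_R
    recs = detect_tolerant(seq, DetectorConfig(quality=1.0))
    agat = [r for r in recs if r.motif.unit == "AGAT"]
    assert [r.span for r in agat] == [24, 24]


def test_scattered_noise_below_quality_yields_nothing():
    # AGAT array with substitutions at 4, 11, 18, 24: every window of
    # >= 20 bp keeps >= 3 errors, so no sub-interval reaches purity 0.9
    arr = list(Motif("AGAT").array(30))
    for pos in (4, 11, 18, 24):
        arr[pos] = "C" if arr[pos] != "C" else "G"
    noisy = "".join(arr)
    assert oracle_tolerant_intervals(noisy, Motif("AGAT"), 0.9, 20) == []
    seq = FLANK_L + noisy + FLANK_R
    recs = detect_tolerant(seq, DetectorConfig(quality=0.9))
    assert [r for r in recs if r.motif.unit == "AGAT" and r.span >= 20] == []


def test_tolerant_quality_one_equals_perfect(rng):
    for _ in range(10):
        seq = random_sequence(rng, 1500)
        pos = int(rng.integers(0, 1400))
        seq = seq[:pos] + Motif("AAG").array(33) + seq[pos + 33:]
        config = DetectorConfig(quality=1.0)
        assert as_set(detect_tolerant(seq, config)) == as_set(detect_perfect(seq, config))


def test_lowering_quality_never_removes_a_locus(rng):
    for _ in range(10):
        seq = random_sequence(rng, 800)
        pos = int(rng.integers(100, 600))
        noisy = Motif("AGAT").array(24) + "T" + Motif("AGAT").array(20)
        seq = seq[:pos] + noisy + seq[pos + len(noisy):]
        perfect = detect_perfect(seq)
        tolerant = detect_tolerant(seq, DetectorConfig(quality=0.9))
        for p in perfect:
            assert any(t.start <= p.start and p.end <= t.end
                       and t.motif == p.motif for t in tolerant), p


def test_planted_noisy_run_recall(rng):
    """Planted runs with purity >= 0.95 and span >= 24 are always found at 0.9."""
    found = total = 0
    for _ in range(25):
        span = int(rng.integers(24, 61))
        u = int(rng.integers(1, 7))
        motif = None
        while motif is None or len(motif) != u:
            unit = random_sequence(rng, u)
            try:
                motif = canonical_motif(unit)
            except Exception:
                continue
            if len(motif) != u:
                motif = None
        arr = list(motif.array(span))
        n_err = int((1 - 0.95) * span)  # at most 5% substitutions
        for pos in rng.choice(span, size=n_err, replace=False):
            arr[pos] = "ACGT"[(("ACGT".index(arr[pos])) + 1) % 4]
        planted = "".join(arr)
        if purity(planted, motif) < 0.95:
            continue
        seq = random_sequence(rng, 300) + planted + random_sequence(rng, 300)
        total += 1
        recs = detect_tolerant(seq, DetectorConfig(quality=0.9))
        if any(r.motif == motif and r.start < 300 + span and 300 < r.end
               for r in recs):
            found += 1
    assert total > 10
    assert found == total


def test_no_tolerant_record_overlaps_n():
    seq = FLANK_L + Motif("AG").array(30) + "NNN" + Motif("AG").array(30) + FLANK_R
    recs = detect_tolerant(seq, DetectorConfig(quality=0.9))
    for r in recs:
        assert "N" not in seq[r.start : r.end]


# --- configuration --------------------------------------------------------

def test_config_validation():
    with pytest.raises(DetectorConfigError):
        DetectorConfig(quality=0.4)
    with pytest.raises(DetectorConfigError):
        DetectorConfig(quality=1.1)
    with pytest.raises(DetectorConfigError):
        DetectorConfig(min_span=10)  # below two units of a hexamer
    with pytest.raises(DetectorConfigError):
        DetectorConfig(unit_lengths=(0, 3))


# --- locus re-measurement -------------------------------------------------

def test_measure_motif_run_basics():
    window = "TTGC" + Motif("AGAT").array(55) + "CCAA"
    assert measure_motif_run(window, Motif("AGAT")) == (4, 59)
    assert measure_motif_run("NNNNNNNN", Motif("AGAT")) is None
    window = "TC" + "GCGGCGGC" + "AT"   # 8 bp array of GCG, phase-shifted
    run = measure_motif_run(window, canonical_motif("GCG"))
    assert run is not None and run[1] - run[0] == 8


def test_measure_motif_run_overlap_filter():
    # a lone unit in the padding does not count as the locus
    window = "AG" + "N" * 30 + "TT"
    assert measure_motif_run(window, Motif("AG"), overlap=(2, 32)) is None
    assert measure_motif_run(window, Motif("AG")) == (0, 2)
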