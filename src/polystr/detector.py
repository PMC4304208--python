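"""Perfect and imperfect STR detection.

Perfect runs are maximal intervals ``s[i..j)`` satisfying ``s[k] == s[k+u]``
for every ``k`` in ``[i, j-u)`` for some unit length ``u``; the character N
never participates in a run. Imperfect ("tolerant") detection reports
regions whose *purity* -- one minus the best-phase edit distance to an ideal
tandem array, divided by the region span -- meets the configured quality
(0.9 allows up to 10% substitution/insertion/deletion noise).

The tolerant detector is seed-and-chain: maximal perfect runs of at least
two units act as atoms; atoms of rotationally equivalent motifs separated by
small gaps are chained while the chained region's purity stays at or above
the quality threshold. Region boundaries coincide with perfect-core
boundaries, so trailing noise is never absorbed into a reported run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .repeat_model import (
    Motif,
    STRRecord,
    canonical_motif,
    motifs_equivalent,
    observed_phase,
)

_N = ord("N")

#: maximum gap (bp) bridged when chaining perfect cores of one motif
CHAIN_GAP = 10


class DetectorConfigError(ValueError):
    """Raised for detector settings outside the supported ranges."""


@dataclass(frozen=True)
class DetectorConfig:
    """Settings for STR discovery.

    quality: 1.0 reports only perfect runs; 0.9 tolerates <10% noise.
        Any value in [0.5, 1.0] is accepted.
    min_span: minimum reported run length in bp (default 20).
    unit_lengths: repeat-unit lengths searched, within 1..6.
    """

    quality: float = 1.0
    min_span: int = 20
    unit_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        if not 0.5 <= self.quality <= 1.0:
            raise DetectorConfigError(f"quality must be in [0.5, 1.0], got {self.quality}")
        if any(u < 1 or u > 6 for u in self.unit_lengths):
            raise DetectorConfigError("unit lengths must lie within 1..6")
        if not self.unit_lengths:
            raise DetectorConfigError("unit_lengths must be non-empty")
        if self.min_span < 2 * max(self.unit_lengths):
            raise DetectorConfigError(
                "min_span must cover at least two units of the largest motif"
            )


def purity(region: str, motif: Motif) -> float:
    """Fraction of ``region`` consistent with an ideal array of ``motif``.

    1 minus the minimum (over the motif's phases) edit distance between the
    region and an equally long ideal tandem array, divided by the region
    length. Equals 1.0 iff the region is a perfect array in some phase.
    N bases count as mismatches (the ideal array never contains N).
    """
    if not region:
        raise ValueError("purity is undefined for an empty region")
    region = region.upper()
    n = len(region)
    best = n
    for phase in range(len(motif)):
        ideal = motif.array(n, phase)
        d = edlib.align(region, ideal, task="distance")["editDistance"]
        if d < best:
            best = d
            if best == 0:
                break
    return 1.0 - best / n


def _true_runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as half-open intervals."""
    if mask.size == 0:
        return []
    padded = np.empty(mask.size + 2, dtype=bool)
    padded[0] = padded[-1] = False
    padded[1:-1] = mask
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return zip(starts.tolist(), ends.tolist())


def perfect_runs(
    sequence: str,
    unit_lengths: Sequence[int] = (1, 2, 3, 4, 5, 6),
    min_span: int = 20,
) -> list[tuple[int, int, int]]:
    """Maximal perfect runs as ``(start, end, unit)`` triples, unsuppressed.

    A run for unit ``u`` needs span >= max(min_span, u + 1) so that at least
    one periodicity comparison supports it. Runs never contain N.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != _N
    out: list[tuple[int, int, int]] = []
    for u in sorted(set(unit_lengths)):
        if arr.size <= u:
            continue
        eq = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
        need = max(min_span, u + 1) - u
        for i, j in _true_runs(eq):
            if j - i < need:
                continue
            # spans below two units leave interior characters uncompared;
            # make sure no N slipped through
            if j - i < u and "N" in seq[i : j + u]:
                continue
            out.append((i, j + u, u))
    return out


def _suppress_nested(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Drop a run for unit u contained in a run for a divisor unit d < u."""
    by_unit: dict[int, list[tuple[int, int]]] = {}
    for i, j, u in runs:
        by_unit.setdefault(u, []).append((i, j))
    kept = []
    for i, j, u in runs:
        nested = False
        for d in range(1, u):
            if u % d:
                continue
            for i2, j2 in by_unit.get(d, ()):
                if i2 <= i and j <= j2:
                    nested = True
                    break
            if nested:
                break
        if not nested:
            kept.append((i, j, u))
    return kept


def _record_from_run(sequence: str, sequence_id: str, i: int, j: int, u: int,
                     pur: float = 1.0) -> STRRecord:
    motif = canonical_motif(sequence[i : i + u])
    phase = observed_phase(sequence[i : i + len(motif)], motif)
    return STRRecord(
        sequence_id=sequence_id, start=i, end=j, motif=motif,
        observed_phase=phase, purity=pur,
    )


def _sort_key(rec: STRRecord):
    return (rec.start, rec.end, rec.unit_length, rec.motif.unit)


def detect_perfect(
    sequence: str, config: DetectorConfig = DetectorConfig(), sequence_id: str = "seq"
) -> list[STRRecord]:
    """All maximal perfect STR runs with span >= ``config.min_span``.

    Output is sorted by start position; purity is 1.0 by construction.
    Runs for a composite unit that sit inside a run for a divisor unit are
    suppressed (a homopolymer is reported once, as its mononucleotide run).
    """
    seq = sequence.upper()
    runs = perfect_runs(seq, config.unit_lengths, config.min_span)
    runs = _suppress_nested(runs)
    records = [_record_from_run(seq, sequence_id, i, j, u) for i, j, u in runs]
    records.sort(key=_sort_key)
    return records


def _chain_atoms(
    seq: str,
    atoms: list[tuple[int, int, int]],
    motif: Motif,
    quality: float,
    max_gap: int = CHAIN_GAP,
) -> list[tuple[int, int, float]]:
    """Maximal qualifying regions over a sorted same-motif atom list.

    From every atom, greedily take the farthest chain end whose full-region
    purity stays >= quality (checking every reachable end, so a transient
    dip inside a noisy patch does not stop the chain). Gaps larger than
    ``max_gap`` or containing N break the chain.
    """
    n = len(atoms)
    regions: list[tuple[int, int, float]] = []
    for s in range(n):
        best_e = s
        best_pur = 1.0
        for e in range(s + 1, n):
            gap_lo, gap_hi = atoms[e - 1][1], atoms[e][0]
            if gap_hi - gap_lo > max_gap or "N" in seq[gap_lo:gap_hi]:
                break
            pur = purity(seq[atoms[s][0] : atoms[e][1]], motif)
            if pur >= quality:
                best_e, best_pur = e, pur
        regions.append((atoms[s][0], atoms[best_e][1], best_pur))
    # keep only regions not contained in another region of this motif
    regions.sort(key=lambda r: (r[0], -r[1]))
    kept: list[tuple[int, int, float]] = []
    for reg in regions:
        if any(k[0] <= reg[0] and reg[1] <= k[1] for k in kept):
            continue
        kept.append(reg)
    return kept


def detect_tolerant(
    sequence: str, config: DetectorConfig, sequence_id: str = "seq"
) -> list[STRRecord]:
    """Imperfect STR detection at ``config.quality`` < 1.0.

    At quality 1.0 this is exactly :func:`detect_perfect`. Otherwise perfect
    cores of >= 2 units are chained per motif while purity permits; reported
    regions satisfy purity >= quality and span >= min_span. Overlapping
    same-motif candidates are deduplicated by containment; candidates nested
    in a divisor-unit candidate are suppressed.
    """
    if config.quality >= 1.0:
        return detect_perfect(sequence, config, sequence_id)
    seq = sequence.upper()
    # fragments: every maximal perfect run showing at least one periodicity
    # comparison; a reported chain must contain a seed core of >= 2 units
    atoms = _suppress_nested(perfect_runs(seq, config.unit_lengths, min_span=2))
    by_motif: dict[Motif, list[tuple[int, int, int]]] = {}
    for i, j, u in atoms:
        m = canonical_motif(seq[i : i + u])
        by_motif.setdefault(m, []).append((i, j, u))
    candidates: list[tuple[int, int, Motif, float]] = []
    for motif, mat in by_motif.items():
        mat.sort()
        u = len(motif)
        if not any(j - i >= 2 * u for i, j, _ in mat):
            continue
        for i, j, pur in _chain_atoms(seq, mat, motif, config.quality):
            has_seed = any(a_i >= i and a_j <= j and a_j - a_i >= 2 * u
                           for a_i, a_j, _ in mat)
            if has_seed and j - i >= config.min_span and pur >= config.quality:
                candidates.append((i, j, motif, pur))
    # suppress candidates nested inside a candidate for a divisor unit,
    # and same-motif containment (already handled per motif, but chains of
    # different motifs may nest when one unit divides the other)
    kept: list[tuple[int, int, Motif, float]] = []
    for i, j, motif, pur in sorted(candidates, key=lambda c: (len(c[2]), c[0])):
        u = len(motif)
        nested = False
        for i2, j2, m2, _ in kept:
            d = len(m2)
            if d < u and u % d == 0 and i2 <= i and j <= j2:
                nested = True
                break
            if m2 == motif and i2 <= i and j <= j2 and (i2, j2) != (i, j):
                nested = True
                break
        if not nested:
            kept.append((i, j, motif, pur))
    records = []
    for i, j, motif, pur in kept:
        phase = observed_phase(seq[i : i + len(motif)], motif) if _matches_rotation(
            seq[i : i + len(motif)], motif
        ) else 0
        records.append(
            STRRecord(sequence_id=sequence_id, start=i, end=j, motif=motif,
                      observed_phase=phase, purity=pur)
        )
    records.sort(key=_sort_key)
    return records


def _matches_rotation(unit: str, motif: Motif) -> bool:
    return len(unit) == len(motif) and unit in motif.unit + motif.unit


def detect(
    sequence: str, config: DetectorConfig = DetectorConfig(), sequence_id: str = "seq"
) -> list[STRRecord]:
    """Dispatch on quality: perfect at 1.0, tolerant below."""
    if config.quality >= 1.0:
        return detect_perfect(sequence, config, sequence_id)
    return detect_tolerant(sequence, config, sequence_id)


def measure_motif_run(
    window: str,
    motif: Motif,
    quality: float = 1.0,
    max_gap: int = CHAIN_GAP,
    overlap: tuple[int, int] | None = None,
) -> tuple[int, int] | None:
    """Longest tandem run of ``motif`` (any phase) inside ``window``.

    Used for genotyping a known locus: no minimum span applies, but a run
    must contain at least one full unit and, when ``overlap`` is given,
    intersect that interval (the lifted locus position) -- a stray unit in
    the flanking padding does not constitute a call. Returns a half-open
    interval in window coordinates, or None when no qualifying run exists.
    At quality < 1.0, perfect fragments are chained as in the detector.
    """
    win = window.upper()
    u = len(motif)
    # seed occurrences of any rotation, then extend by periodicity
    rotations = {motif.rotation(p) for p in range(u)}
    seeds: set[tuple[int, int]] = set()
    for rot in rotations:
        start = win.find(rot)
        while start != -1:
            i, j = start, start + u
            while i > 0 and win[i - 1] == win[i - 1 + u] and win[i - 1] != "N":
                i -= 1
            while j < len(win) and win[j] == win[j - u] and win[j] != "N":
                j += 1
            seeds.add((i, j))
            start = win.find(rot, start + 1)
    if not seeds:
        return None
    atoms = sorted({(i, j, u) for i, j in seeds})
    # drop atoms contained in other atoms
    atoms = [a for a in atoms if not any(
        b[0] <= a[0] and a[1] <= b[1] and a != b for b in atoms)]
    if quality < 1.0 and len(atoms) > 1:
        regions = _chain_atoms(win, atoms, motif, quality, max_gap)
    else:
        regions = [(i, j, 1.0) for i, j, _ in atoms]
    if overlap is not None:
        lo, hi = overlap
        regions = [r for r in regions if r[0] < hi and lo < r[1]]
    if not regions:
        return None
    best = max(regions, key=lambda r: (r[1] - r[0], -r[0]))
    return (best[0], best[1])
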