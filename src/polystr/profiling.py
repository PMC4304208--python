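"""Per-individual STR profiles, the unified template, and genotyping.

Each calibrated individual sequence is scanned for STRs and every detected
run is lifted onto reference coordinates, giving an individual profile.
Fragmented same-motif segments separated by small gaps are re-merged. The
union of all individual profiles plus the reference profile -- clustered by
rotational motif equivalence and >= 1 bp reference-interval overlap --
yields the template profile: the complete catalogue of repeat loci observed
in any genome. Every template locus is then re-measured in every individual
with no minimum-span threshold, distinguishing a genuinely absent repeat
(span 0) from a locus obscured by missing consensus data (N => missing,
rendered "0*" in reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .calibration import CalibratedPair, CoordMap
from .detector import CHAIN_GAP, DetectorConfig, detect, measure_motif_run, purity
from .repeat_model import Motif, STRRecord, motifs_equivalent, repeat_number
from .statistics import PolymorphismRecord, polymorphism_record

#: default maximum gap bridged when re-merging fragmented segments
MERGE_MAX_GAP = 10
#: merged regions may fall this far below the detection quality
MERGE_QUALITY_SLACK = 0.05


@dataclass
class STRProfile:
    """All STR records of one individual for one gene, on reference coords."""

    individual_id: str
    gene_id: str
    chromosome_id: str
    quality: float
    records: list[STRRecord]
    sequence: str = ""

    def sorted_records(self) -> list[STRRecord]:
        return sorted(self.records, key=lambda r: (r.ref_start, r.ref_end, r.motif.unit))


def build_profile(
    pair: CalibratedPair,
    coord_map: CoordMap,
    config: DetectorConfig,
    individual_id: str,
    chromosome_id: str = "chr",
) -> STRProfile:
    """Detect STRs in a calibrated sequence and map them onto the reference."""
    records = detect(pair.target_seq, config, sequence_id=individual_id)
    for rec in records:
        lo, hi = coord_map.map_interval((rec.start, rec.end))
        rec.ref_start = lo + pair.ref_offset
        rec.ref_end = hi + pair.ref_offset
    records.sort(key=lambda r: (r.ref_start, r.ref_end))
    return STRProfile(
        individual_id=individual_id,
        gene_id=pair.gene_id,
        chromosome_id=chromosome_id,
        quality=config.quality,
        records=records,
        sequence=pair.target_seq,
    )


def merge_adjacent(
    profile: STRProfile,
    max_gap: int = MERGE_MAX_GAP,
    quality: Optional[float] = None,
) -> STRProfile:
    """Re-merge fragmented same-motif segments.

    Two consecutive records of rotationally equivalent motifs merge when
    their reference-interval gap is at most ``max_gap`` bp and the merged
    target region keeps purity >= quality - 0.05; overlapping same-motif
    records are unioned unconditionally. Merging proceeds left to right and
    is transitive across chains of mergeable segments.
    """
    q = profile.quality if quality is None else quality
    by_motif: dict[str, list[STRRecord]] = {}
    for rec in profile.sorted_records():
        by_motif.setdefault(rec.motif.unit, []).append(rec)
    merged_all: list[STRRecord] = []
    for recs in by_motif.values():
        cur = recs[0]
        for nxt in recs[1:]:
            gap = nxt.ref_start - cur.ref_end
            if gap <= 0:
                merge_ok = True
            elif gap <= max_gap:
                region = profile.sequence[cur.start : nxt.end]
                merge_ok = bool(region) and purity(region, cur.motif) >= q - MERGE_QUALITY_SLACK
            else:
                merge_ok = False
            if merge_ok:
                start = min(cur.start, nxt.start)
                end = max(cur.end, nxt.end)
                region = profile.sequence[start:end]
                cur = replace(
                    cur,
                    start=start,
                    end=end,
                    purity=purity(region, cur.motif) if region else cur.purity,
                    ref_start=min(cur.ref_start, nxt.ref_start),
                    ref_end=max(cur.ref_end, nxt.ref_end),
                )
            else:
                merged_all.append(cur)
                cur = nxt
        merged_all.append(cur)
    merged_all.sort(key=lambda r: (r.ref_start, r.ref_end))
    return STRProfile(
        individual_id=profile.individual_id,
        gene_id=profile.gene_id,
        chromosome_id=profile.chromosome_id,
        quality=profile.quality,
        records=merged_all,
        sequence=profile.sequence,
    )


@dataclass(frozen=True)
class TemplateLocus:
    """One locus of the unified template profile."""

    locus_id: str
    motif: Motif
    ref_interval: tuple[int, int]
    contributors: tuple[str, ...]
    gene_id: str = ""
    chromosome_id: str = ""

    @property
    def unit_length(self) -> int:
        return len(self.motif)


def build_template(profiles: Iterable[STRProfile]) -> list[TemplateLocus]:
    """Union of all profiles into template loci.

    Records across profiles are linked when their motifs are rotationally
    equivalent and their reference intervals overlap by at least 1 bp;
    single-linkage clusters become loci whose interval is the union of the
    members. A record seen in only one genome still founds a locus.
    """
    items: list[tuple[str, int, int, str, str, str]] = []
    for prof in profiles:
        for rec in prof.records:
            items.append((rec.motif.unit, rec.ref_start, rec.ref_end,
                          prof.individual_id, prof.gene_id, prof.chromosome_id))
    loci: list[TemplateLocus] = []
    by_motif: dict[str, list[tuple[str, int, int, str, str, str]]] = {}
    for it in items:
        by_motif.setdefault(it[0], []).append(it)
    for unit, group in sorted(by_motif.items()):
        group.sort(key=lambda it: (it[1], it[2]))
        cluster: list[tuple[str, int, int, str, str, str]] = []
        cluster_end = None
        def flush() -> None:
            if not cluster:
                return
            lo = min(it[1] for it in cluster)
            hi = max(it[2] for it in cluster)
            contributors = tuple(sorted({it[3] for it in cluster}))
            gene_id = cluster[0][4]
            chrom = cluster[0][5]
            loci.append(TemplateLocus(
                locus_id=f"{chrom}:{lo}-{hi}:{unit}",
                motif=Motif(unit),
                ref_interval=(lo, hi),
                contributors=contributors,
                gene_id=gene_id,
                chromosome_id=chrom,
            ))
        for it in group:
            if cluster and it[1] < cluster_end:
                cluster.append(it)
                cluster_end = max(cluster_end, it[2])
            else:
                flush()
                cluster = [it]
                cluster_end = it[2]
        flush()
    loci.sort(key=lambda l: (l.chromosome_id, l.ref_interval, l.motif.unit))
    return loci


@dataclass(frozen=True)
class LocusCall:
    """A per-individual measurement at a template locus.

    status 'called' carries a span (possibly 0 when the repeat is absent
    from a clean window); status 'missing' marks windows obscured by N with
    no measurable run (rendered "0*").
    """

    individual_id: str
    locus_id: str
    status: str
    span: Optional[int] = None
    repeat: Optional[Fraction] = None

    def __post_init__(self) -> None:
        if self.status not in ("called", "missing"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "missing" and (self.span is not None or self.repeat is not None):
            raise ValueError("missing calls carry no span or repeat number")
        if self.status == "called" and self.span is None:
            raise ValueError("called status requires a span")


def genotype_locus(
    locus: TemplateLocus,
    pair: CalibratedPair,
    coord_map: CoordMap,
    individual_id: str,
    quality: float = 1.0,
) -> Optional[LocusCall]:
    """Re-measure a template locus in one individual.

    The locus interval is lifted to the individual and widened by one unit
    length per side to absorb boundary phase shifts; the longest tandem run
    of the locus motif inside the window is measured with no minimum span.
    Returns None when the window cannot be mapped (the locus is excluded
    for this individual and logged by the pipeline).
    """
    u = locus.unit_length
    lo = locus.ref_interval[0] - pair.ref_offset
    hi = locus.ref_interval[1] - pair.ref_offset
    ref_len = len(pair.ref_seq)
    if hi <= 0 or lo >= ref_len:
        return None
    lo, hi = max(0, lo), min(ref_len, hi)
    t_lo, t_hi = coord_map.map_ref_interval((lo, hi))
    w0 = max(0, t_lo - u)
    w1 = min(len(pair.target_seq), t_hi + u)
    window = pair.target_seq[w0:w1]
    if not window:
        return None
    run = measure_motif_run(window, locus.motif, quality=quality,
                            overlap=(t_lo - w0, max(t_hi - w0, t_lo - w0 + 1)))
    if run is not None:
        # an insertion placed at the run edge by the aligner can push part
        # of the run outside the lifted window: extend by periodicity
        seq = pair.target_seq
        a, b = w0 + run[0], w0 + run[1]
        while a > 0 and a - 1 + u < len(seq) and seq[a - 1] != "N" and seq[a - 1] == seq[a - 1 + u]:
            a -= 1
        while b < len(seq) and seq[b] != "N" and seq[b] == seq[b - u]:
            b += 1
        span = b - a
        return LocusCall(individual_id, locus.locus_id, "called",
                         span=span, repeat=repeat_number(span, u))
    if "N" in window.upper():
        return LocusCall(individual_id, locus.locus_id, "missing")
    return LocusCall(individual_id, locus.locus_id, "called",
                     span=0, repeat=Fraction(0))


def call_polymorphisms(
    template: Sequence[TemplateLocus],
    calls: Iterable[LocusCall],
) -> list[PolymorphismRecord]:
    """Classify every template locus as conserved/polymorphic/indeterminate.

    Conserved: all non-missing spans equal. Polymorphic: any two spans
    differ by >= 1 bp; the variation degree is the largest pairwise
    difference. Loci with fewer than two non-missing calls stay
    indeterminate (deviation fields None).
    """
    by_locus: dict[str, dict[str, Optional[int]]] = {}
    for call in calls:
        by_locus.setdefault(call.locus_id, {})[call.individual_id] = (
            call.span if call.status == "called" else None)
    records: list[PolymorphismRecord] = []
    for locus in template:
        locus_calls = by_locus.get(locus.locus_id, {})
        records.append(polymorphism_record(
            locus_id=locus.locus_id,
            gene_id=locus.gene_id,
            chromosome_id=locus.chromosome_id,
            motif=locus.motif,
            calls=locus_calls,
            ref_interval=locus.ref_interval,
        ))
    return records
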