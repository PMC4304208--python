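"""Deviation metrics, density/occurrence summaries, and candidate selection.

At a locus genotyped across n individuals with repeat spans in bp, the two
headline deviation statistics are

    Max.Dev = max(spans) - min(spans)
    Avg.Dev = sum over unordered pairs |span_i - span_j| / C(n, 2)

A locus is polymorphic when Max.Dev >= 1 bp and conserved when all spans are
equal; loci with fewer than two non-missing calls are indeterminate and
excluded from every summary. Gene-set summaries report the polymorphic STR
density TNpSTR/TLgene (loci per Mbp) and the occurrence ratio TNpSTR/TNSTR
(percent). Manhattan-style normalization divides per-locus quartile bounds
(scaled by +/-1.25) and extremes by the median repeat number, flagging loci
whose normalized maximum exceeds a chosen threshold as biomarker candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .repeat_model import Motif, StatsSummary

BP_PER_MBP = 10**6


class IndeterminateDeviation(ValueError):
    """Fewer than two non-missing calls: deviations are undefined."""


class UndefinedRatio(ZeroDivisionError):
    """A summary ratio with a zero denominator."""


def max_dev(spans: Sequence[float]) -> float:
    """Largest pairwise span difference in bp (requires >= 2 values)."""
    if len(spans) < 2:
        raise IndeterminateDeviation(f"need >= 2 spans, got {len(spans)}")
    return float(max(spans) - min(spans))


def avg_dev(spans: Sequence[float]) -> float:
    """Mean absolute pairwise span difference over all C(n,2) pairs.

    Computed via the sorted-prefix identity
    ``sum_{i<j} |x_i - x_j| = sum_i (2i - n + 1) * x_(i)``; the test suite
    checks it against direct pair enumeration.
    """
    n = len(spans)
    if n < 2:
        raise IndeterminateDeviation(f"need >= 2 spans, got {n}")
    xs = np.sort(np.asarray(spans, dtype=float))
    coeff = 2 * np.arange(n) - n + 1
    total = float(np.dot(coeff, xs))
    return total / (n * (n - 1) / 2)


def round_half_up(value: float, places: int) -> float:
    """Decimal half-up rounding used for report parity."""
    q = Decimal(repr(value)).quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP)
    return float(q)


def density(tn_pstr: int, tl_gene_mbp: float, places: int = 4) -> float:
    """Polymorphic STR density in loci per Mbp (half-up rounded)."""
    if tl_gene_mbp <= 0:
        raise UndefinedRatio("total gene length must be positive")
    return round_half_up(tn_pstr / tl_gene_mbp, places)


def occurrence_ratio(tn_pstr: int, tn_str: int, places: int = 2) -> float:
    """Polymorphic share of all STRs, in percent (half-up rounded)."""
    if tn_str <= 0:
        raise UndefinedRatio("total STR count must be positive")
    return round_half_up(100.0 * tn_pstr / tn_str, places)


def fold_conserved(tn_str: int, tn_pstr: int) -> float:
    """Conserved-to-polymorphic fold change (TNSTR - TNpSTR) / TNpSTR."""
    if tn_pstr <= 0:
        raise UndefinedRatio("fold change undefined without polymorphic STRs")
    return (tn_str - tn_pstr) / tn_pstr


@dataclass
class PolymorphismRecord:
    """Per-locus polymorphism call across all individuals.

    ``calls`` maps individual id to span in bp (None for missing). For
    indeterminate loci (fewer than two non-missing calls) the deviation
    fields are None and ``is_polymorphic`` is None.
    """

    locus_id: str
    gene_id: str
    chromosome_id: str
    motif: Motif
    calls: dict[str, Optional[int]]
    is_polymorphic: Optional[bool] = None
    variation_degree: Optional[float] = None
    max_dev: Optional[float] = None
    avg_dev: Optional[float] = None
    region_code: Optional[int] = None
    ref_interval: Optional[tuple[int, int]] = None
    position: int = 0

    def __post_init__(self) -> None:
        if self.max_dev is not None and self.avg_dev is not None:
            if not self.max_dev >= self.avg_dev >= 0:
                raise ValueError("max_dev >= avg_dev >= 0 violated")
            if self.is_polymorphic != (self.max_dev >= 1):
                raise ValueError("is_polymorphic must mirror max_dev >= 1 bp")

    @property
    def indeterminate(self) -> bool:
        return self.is_polymorphic is None

    @property
    def called_spans(self) -> list[int]:
        return [s for s in self.calls.values() if s is not None]

    @property
    def span_length(self) -> int:
        if self.ref_interval is None:
            return 0
        return self.ref_interval[1] - self.ref_interval[0]


def polymorphism_record(
    locus_id: str,
    gene_id: str,
    chromosome_id: str,
    motif: Motif,
    calls: Mapping[str, Optional[int]],
    region_code: Optional[int] = None,
    ref_interval: Optional[tuple[int, int]] = None,
) -> PolymorphismRecord:
    """Build a record, computing deviations from the non-missing calls."""
    spans = [s for s in calls.values() if s is not None]
    rec = PolymorphismRecord(
        locus_id=locus_id, gene_id=gene_id, chromosome_id=chromosome_id,
        motif=motif, calls=dict(calls), region_code=region_code,
        ref_interval=ref_interval,
        position=ref_interval[0] if ref_interval else 0,
    )
    if len(spans) >= 2:
        md = max_dev(spans)
        rec.max_dev = md
        rec.avg_dev = avg_dev(spans)
        rec.variation_degree = md
        rec.is_polymorphic = md >= 1
    return rec


def summarize_gene_set(
    records: Iterable[PolymorphismRecord],
    gene_lengths_bp: Mapping[str, int],
) -> tuple[StatsSummary, dict[str, float]]:
    """Counts and ratios for one gene set.

    TLSTR sums reference locus lengths; TLgene sums the supplied gene
    lengths; indeterminate loci are excluded from all counts. Returns the
    summary plus the derived density (per Mbp, 4 decimals) and occurrence
    ratio (percent, 2 decimals).
    """
    recs = [r for r in records if not r.indeterminate]
    tn_str = len(recs)
    tn_pstr = sum(1 for r in recs if r.is_polymorphic)
    summary = StatsSummary(
        TLSTR=sum(r.span_length for r in recs) / BP_PER_MBP,
        TLgene=sum(gene_lengths_bp.values()) / BP_PER_MBP,
        TNgene=len(gene_lengths_bp),
        TNSTR=tn_str,
        TNpSTR=tn_pstr,
        TNcSTR=tn_str - tn_pstr,
    )
    ratios: dict[str, float] = {}
    if summary.TLgene > 0:
        ratios["density_per_mbp"] = density(tn_pstr, summary.TLgene)
    if tn_str > 0:
        ratios["occurrence_pct"] = occurrence_ratio(tn_pstr, tn_str)
    return summary, ratios


def distribution_matrix(
    records: Iterable[PolymorphismRecord],
    bp_range: tuple[int, int] = (20, 84),
    group_by: str = "chromosome",
    kind: str = "polymorphic",
) -> pd.DataFrame:
    """Histogram matrices of STR variation or conservation.

    group_by='chromosome': one row per chromosome. For kind='polymorphic'
    the columns bin loci by variation degree (bp) over ``bp_range`` and
    cells hold percentages of that chromosome's determinate loci; for
    kind='conserved' loci are binned by their reference span length. The
    'accumulated' column sums the row, and the polymorphic and conserved
    accumulated percentages total 100 per chromosome.

    group_by='unit_region': one row per (unit length, region code) pair and
    cells count distinct genes carrying a polymorphic locus in the bin.
    """
    lo, hi = bp_range
    bins = list(range(lo, hi + 1))
    recs = [r for r in records if not r.indeterminate]
    if group_by == "chromosome":
        groups = sorted({r.chromosome_id for r in recs})
        mat = pd.DataFrame(0.0, index=groups, columns=bins + ["accumulated"])
        for chrom in groups:
            sub = [r for r in recs if r.chromosome_id == chrom]
            total = len(sub)
            if kind == "polymorphic":
                chosen = [r for r in sub if r.is_polymorphic]
                values = [min(max(int(r.variation_degree), lo), hi) for r in chosen]
            elif kind == "conserved":
                chosen = [r for r in sub if not r.is_polymorphic]
                values = [min(max(r.span_length, lo), hi) for r in chosen]
            else:
                raise ValueError(f"unknown kind {kind!r}")
            for v in values:
                mat.loc[chrom, v] += 100.0 / total
            mat.loc[chrom, "accumulated"] = 100.0 * len(chosen) / total if total else 0.0
        return mat
    if group_by == "unit_region":
        idx = pd.MultiIndex.from_product(
            [range(1, 7), range(1, 8)], names=["unit_length", "region_code"])
        mat = pd.DataFrame(0, index=idx, columns=bins)
        for r in recs:
            if not r.is_polymorphic or r.region_code is None:
                continue
            v = min(max(int(r.variation_degree), lo), hi)
            key = (len(r.motif), r.region_code)
            mat.loc[key, v] += 1
        return mat
    raise ValueError(f"unknown group_by {group_by!r}")


@dataclass(frozen=True)
class ManhattanPoint:
    """Normalized per-locus variation summary for candidate selection."""

    locus_id: str
    chromosome_id: str
    position: int
    median: float
    q1: float
    q3: float
    normalized_upper: float
    normalized_lower: float
    normalized_max: float
    normalized_min: float


def manhattan_points(
    records: Iterable[PolymorphismRecord],
    unit_lengths: Optional[Mapping[str, int]] = None,
) -> list[ManhattanPoint]:
    """Quartile/extreme summaries of per-individual repeat numbers.

    Upper/lower bounds multiply the upper/lower quartile by +/-1.25 and all
    four summaries are normalized by the median across individuals.
    Quartiles use inclusive linear interpolation. Loci with median 0 (or
    fewer than two calls) are skipped with a warning.
    """
    points: list[ManhattanPoint] = []
    for rec in records:
        spans = rec.called_spans
        if len(spans) < 2:
            continue
        u = len(rec.motif)
        reps = np.asarray(spans, dtype=float) / u
        q1, med, q3 = np.quantile(reps, [0.25, 0.5, 0.75])
        if med <= 0:
            warnings.warn(f"locus {rec.locus_id}: median repeat number 0, skipped")
            continue
        points.append(ManhattanPoint(
            locus_id=rec.locus_id,
            chromosome_id=rec.chromosome_id,
            position=rec.position,
            median=float(med), q1=float(q1), q3=float(q3),
            normalized_upper=float(1.25 * q3 / med),
            normalized_lower=float(-1.25 * q1 / med),
            normalized_max=float(reps.max() / med),
            normalized_min=float(reps.min() / med),
        ))
    return points


def select_candidates(
    points: Iterable[ManhattanPoint], threshold: float
) -> list[ManhattanPoint]:
    """Loci whose normalized maximum reaches ``threshold``, by position."""
    chosen = [p for p in points if p.normalized_max >= threshold]
    return sorted(chosen, key=lambda p: (p.chromosome_id, p.position))
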