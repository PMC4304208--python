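"""Genetic-region assignment and biomarker classification.

Loci are placed into one of seven region classes per transcript by their
midpoint: 1=Intron, 2=Upstream, 3=Downstream, 4=5'UTR, 5=Coding, 6=3'UTR,
7=Undefined exon (exon of a non-coding transcript). Upstream/downstream and
UTR sides are strand-aware. The gene-level summary code comes from the
longest transcript.

Polymorphic loci are classified against a two-trio pedigree into biomarker
types: INDIVIDUAL (all six family members pairwise distinct -- distinguishes
every person), INHERITANCE (each child's span matches a parent's and the
locus is polymorphic -- Mendelian-consistent family markers), and GROUP
(constant within each family but different between families). A locus whose
maximum deviation is exactly 1 bp additionally carries a SNP flag. The
reference pseudo-individual participates in polymorphism statistics but
never in family classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence

FLANK = 7000

INDIVIDUAL = "INDIVIDUAL"
INHERITANCE = "INHERITANCE"
GROUP = "GROUP"

ROLES = ("father", "mother", "child")


class RegionCode(IntEnum):
    INTRON = 1
    UPSTREAM = 2
    DOWNSTREAM = 3
    UTR5 = 4
    CODING = 5
    UTR3 = 6
    UNDEFINED_EXON = 7


REGION_NAMES = {
    RegionCode.INTRON: "Intron",
    RegionCode.UPSTREAM: "Upstream",
    RegionCode.DOWNSTREAM: "Downstream",
    RegionCode.UTR5: "5'UTR",
    RegionCode.CODING: "Coding",
    RegionCode.UTR3: "3'UTR",
    RegionCode.UNDEFINED_EXON: "Undefined exon",
}


class AnnotationError(ValueError):
    """Locus outside the annotated gene territory, or a malformed model."""


class ClassificationError(ValueError):
    """Pedigree incomplete or inconsistent with the supplied calls."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sorted, non-overlapping exons with an optional CDS."""

    gene_id: str
    transcript_id: str
    chromosome_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        ex = sorted(self.exons)
        if tuple(ex) != self.exons or any(
                ex[i][1] > ex[i + 1][0] for i in range(len(ex) - 1)):
            raise AnnotationError(f"{self.transcript_id}: exons must be sorted and disjoint")
        for c0, c1 in self.cds:
            if not any(e0 <= c0 and c1 <= e1 for e0, e1 in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS segment [{c0},{c1}) outside exons")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_interval(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        cds = sorted(self.cds)
        return (cds[0][0], cds[-1][1])

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) exonic intervals, strand-aware."""
        ci = self.cds_interval
        if ci is None:
            return ([], [])
        left, right = [], []
        for e0, e1 in self.exons:
            if e0 < ci[0]:
                left.append((e0, min(e1, ci[0])))
            if e1 > ci[1]:
                right.append((max(e0, ci[1]), e1))
        if self.strand == "+":
            return (left, right)
        return (right, left)


def _contains(intervals: Iterable[tuple[int, int]], pos: int) -> bool:
    return any(a <= pos < b for a, b in intervals)


def _transcript_region(tx: TranscriptModel, mid: int, flank: int) -> RegionCode:
    t0, t1 = tx.interval
    if t0 <= mid < t1:
        if _contains(tx.cds, mid):
            return RegionCode.CODING
        utr5, utr3 = tx.utr_intervals()
        if _contains(utr5, mid):
            return RegionCode.UTR5
        if _contains(utr3, mid):
            return RegionCode.UTR3
        if _contains(tx.exons, mid):
            return RegionCode.UNDEFINED_EXON if not tx.is_coding else RegionCode.INTRON
        return RegionCode.INTRON
    before = t0 - flank <= mid < t0
    after = t1 <= mid < t1 + flank
    if before or after:
        upstream_side = before if tx.strand == "+" else after
        return RegionCode.UPSTREAM if upstream_side else RegionCode.DOWNSTREAM
    raise AnnotationError(f"position {mid} outside {tx.transcript_id} +/- {flank} bp")


def assign_region(
    locus_interval: tuple[int, int],
    transcripts: Sequence[TranscriptModel],
    gene_interval: Optional[tuple[int, int]] = None,
    flank: int = FLANK,
) -> tuple[dict[str, RegionCode], RegionCode]:
    """Region code per transcript plus the gene-level summary code.

    The locus midpoint decides the region (loci straddling a boundary take
    the midpoint's class); the summary comes from the longest transcript.
    """
    if not transcripts:
        raise AnnotationError("no transcripts supplied")
    mid = (locus_interval[0] + locus_interval[1]) // 2
    if gene_interval is None:
        gene_interval = (min(t.interval[0] for t in transcripts),
                         max(t.interval[1] for t in transcripts))
    if not gene_interval[0] - flank <= mid < gene_interval[1] + flank:
        raise AnnotationError(
            f"locus midpoint {mid} outside gene {gene_interval} +/- {flank} bp")
    per_tx = {t.transcript_id: _transcript_region(t, mid, flank) for t in transcripts}
    longest = max(transcripts, key=lambda t: (t.length, t.transcript_id))
    return per_tx, per_tx[longest.transcript_id]


@dataclass(frozen=True)
class Pedigree:
    """Two trios plus an optional reference pseudo-individual.

    ``members`` maps individual id to (family_id, role); the reference is
    excluded from family logic.
    """

    members: Mapping[str, tuple[str, str]]
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        families: dict[str, set[str]] = {}
        for ind, (fam, role) in self.members.items():
            if role not in ROLES:
                raise ClassificationError(f"{ind}: unknown role {role!r}")
            families.setdefault(fam, set())
            if role in families[fam]:
                raise ClassificationError(f"family {fam}: duplicate role {role}")
            families[fam].add(role)
        for fam, roles in families.items():
            if roles != set(ROLES):
                raise ClassificationError(
                    f"family {fam} must have father, mother and child; has {sorted(roles)}")
        object.__setattr__(self, "members", dict(self.members))

    @property
    def families(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for ind, (fam, role) in self.members.items():
            out.setdefault(fam, {})[role] = ind
        return out

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.members)


def classify_biomarker(
    calls: Mapping[str, Optional[int]],
    pedigree: Pedigree,
    is_polymorphic: bool,
    max_dev: Optional[float] = None,
) -> tuple[frozenset[str], bool]:
    """Biomarker type set and SNP flag for one locus.

    ``calls`` maps individual id to span in bp (missing => None). All six
    family members must be called; otherwise the type set is empty. The
    SNP flag marks loci whose maximum deviation is exactly 1 bp.
    """
    fams = pedigree.families
    spans: dict[str, int] = {}
    for fam, roles in fams.items():
        for role, ind in roles.items():
            if ind not in calls:
                raise ClassificationError(f"no call supplied for {ind} ({fam} {role})")
            spans[ind] = calls[ind]
    if any(v is None for v in spans.values()):
        return frozenset(), False
    values = list(spans.values())
    types: set[str] = set()
    if len(set(values)) == len(values):
        types.add(INDIVIDUAL)
    child_matches = all(
        spans[roles["child"]] in (spans[roles["father"]], spans[roles["mother"]])
        for roles in fams.values())
    if child_matches and is_polymorphic:
        types.add(INHERITANCE)
    fam_values = []
    constant = True
    for roles in fams.values():
        vals = {spans[ind] for ind in roles.values()}
        if len(vals) != 1:
            constant = False
            break
        fam_values.append(next(iter(vals)))
    if constant and len(set(fam_values)) == len(fam_values) and len(fam_values) > 1:
        types.add(GROUP)
    snp_flag = max_dev is not None and max_dev == 1
    return frozenset(types), snp_flag
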