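"""Synthetic reference + two-trio personal genomes with planted STR loci.

The generator emulates the seven-genome study design: one reference genome
and six individuals forming two father/mother/child trios. Random
background chromosomes carry annotated genes (exons, CDS, UTRs); perfect
STR arrays are planted at recorded loci inside and around the genes.
Parents draw per-locus repeat spans independently from an
expansion/contraction distribution around the reference span; each child
inherits, locus by locus, the span of one uniformly chosen parent. SNP and
small-indel noise is sprinkled outside a 10 bp guard zone around every
locus, and whole loci can be obscured by N runs (emulating consensus
drop-out), with every planted value and missing flag recorded in a truth
table for parameter-recovery testing.

The generator is deterministic end to end under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation import Pedigree, TranscriptModel
from .profiling import LocusCall, TemplateLocus
from .repeat_model import Motif, canonical_motif, motifs_equivalent
from .statistics import PolymorphismRecord, avg_dev, max_dev

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FAMILIES = ("F1", "F2")
ROLE_ORDER = ("father", "mother", "child")
INDIVIDUALS = tuple(f"{fam}_{role}" for fam in FAMILIES for role in ROLE_ORDER)
REFERENCE_ID = "reference"

#: SNP/indel noise never lands within this many bp of a planted locus
LOCUS_GUARD = 10


def make_pedigree() -> Pedigree:
    return Pedigree({f"{fam}_{role}": (fam, role)
                     for fam in FAMILIES for role in ROLE_ORDER})


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the two-trio setting: 50 genes across 2 chromosomes
    with 3 planted loci per gene (150 loci). Noise defaults are a human-like
    SNP rate of 1e-3, small indels at 1e-4, and a 2% chance per
    (locus, individual) that consensus drop-out masks the locus with N.
    """

    n_chromosomes: int = 2
    n_genes: int = 50
    loci_per_gene: int = 3
    gene_length_range: tuple[int, int] = (1500, 3000)
    flank: int = 7000
    anchor: int = 500
    motif_length_weights: tuple[float, ...] = (2, 3, 2, 2, 1, 1)
    base_span_range: tuple[int, int] = (28, 60)
    #: probabilities of a parent allele differing by -2..+2 units
    expansion_probs: tuple[float, ...] = (0.10, 0.15, 0.50, 0.15, 0.10)
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    indel_max: int = 5
    n_mask_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.snp_rate, self.indel_rate, self.n_mask_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(self.expansion_probs) - 1.0) > 1e-9:
            raise ValueError("expansion probabilities must sum to 1")
        if self.n_genes < 1 or self.loci_per_gene < 1:
            raise ValueError("need at least one gene and one locus per gene")


@dataclass
class TruthLocus:
    """Ground truth for one planted locus."""

    locus_id: str
    gene_id: str
    chromosome_id: str
    ref_interval: tuple[int, int]
    motif: str
    ref_span: int
    spans: dict[str, int] = field(default_factory=dict)
    missing: dict[str, bool] = field(default_factory=dict)


@dataclass
class SimTruth:
    """All planted loci plus per-individual variant bookkeeping."""

    loci: list[TruthLocus] = field(default_factory=list)
    snp_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    indel_positions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def by_id(self) -> dict[str, TruthLocus]:
        return {t.locus_id: t for t in self.loci}


@dataclass
class SimReference:
    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    truth: SimTruth

    @property
    def gene_intervals(self) -> dict[str, tuple[str, tuple[int, int]]]:
        out: dict[str, tuple[str, tuple[int, int]]] = {}
        for tx in self.transcripts:
            chrom = tx.chromosome_id
            iv = tx.interval
            if tx.gene_id in out:
                _, old = out[tx.gene_id]
                iv = (min(old[0], iv[0]), max(old[1], iv[1]))
            out[tx.gene_id] = (chrom, iv)
        return out


def _random_motif(rng: np.random.Generator, weights: Sequence[float]) -> Motif:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    while True:
        u = int(rng.choice(np.arange(1, 7), p=w))
        unit = "".join(chr(b) for b in rng.choice(_BASES, size=u))
        motif = canonical_motif(unit)
        if len(motif) == u:
            return motif


def _fix_boundary(seq: bytearray, pos: int, avoid: Iterable[int],
                  rng: np.random.Generator) -> None:
    """Set seq[pos] to a base outside ``avoid`` (periodicity breakers)."""
    avoid_set = set(avoid)
    choices = [b for b in _BASES.tolist() if b not in avoid_set]
    if seq[pos] in avoid_set:
        seq[pos] = int(rng.choice(choices))


def simulate_reference(config: SimConfig) -> SimReference:
    """Random annotated chromosomes with perfect STR arrays planted.

    Raises ValueError when the requested genes cannot be packed. Planted
    run boundaries are adjusted so each array is exactly maximal (the
    flanking base never continues the periodicity), and flanks within
    30 bp of a locus carry no other repeat structure by construction
    (loci are spaced >= 100 bp apart in STR-free random background).
    """
    rng = np.random.default_rng(config.seed)
    ext = config.flank + config.anchor
    genes_per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        genes_per_chrom[i] += 1
    if any(n < 1 for n in genes_per_chrom):
        raise ValueError("more chromosomes than genes: infeasible packing")
    sequences: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    truth = SimTruth()
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        gene_layout: list[tuple[str, int, int]] = []
        cursor = ext + 100
        for _ in range(genes_per_chrom[ci]):
            gene_no += 1
            glen = int(rng.integers(*config.gene_length_range))
            gene_layout.append((f"G{gene_no:04d}", cursor, cursor + glen))
            cursor += glen + 2 * ext + 200
        chrom_len = cursor + 100
        arr = bytearray(rng.choice(_BASES, size=chrom_len).tobytes())
        for gene_id, g0, g1 in gene_layout:
            transcripts.append(_make_transcript(gene_id, chrom, g0, g1, rng))
            loci = _place_loci(config, rng, g0, g1)
            for li, pos in enumerate(loci, start=1):
                motif = _random_motif(rng, config.motif_length_weights)
                u = len(motif)
                span = int(rng.integers(*config.base_span_range))
                span = max(span, 2 * u + 2)
                allele = motif.array(span).encode("ascii")
                arr[pos : pos + span] = allele
                # keep the planted array exactly maximal
                _fix_boundary(arr, pos - 1, {arr[pos - 1 + u], arr[pos - 2]}, rng)
                _fix_boundary(arr, pos + span, {arr[pos + span - u], arr[pos + span + 1]}, rng)
                truth.loci.append(TruthLocus(
                    locus_id=f"{chrom}:{pos}:{motif}",
                    gene_id=gene_id,
                    chromosome_id=chrom,
                    ref_interval=(pos, pos + span),
                    motif=str(motif),
                    ref_span=span,
                ))
        sequences[chrom] = arr.decode("ascii")
    return SimReference(sequences=sequences, transcripts=transcripts, truth=truth)


def _make_transcript(gene_id: str, chrom: str, g0: int, g1: int,
                     rng: np.random.Generator) -> TranscriptModel:
    """Three exons with a CDS from mid-exon1 to mid-exon3."""
    glen = g1 - g0
    e_len = max(120, glen // 6)
    exon1 = (g0, g0 + e_len)
    exon3 = (g1 - e_len, g1)
    mid = (g0 + g1) // 2
    exon2 = (mid - e_len // 2, mid + e_len // 2)
    strand = "+" if rng.integers(2) == 0 else "-"
    cds_lo = exon1[0] + e_len // 2
    cds_hi = exon3[1] - e_len // 2
    cds = tuple(
        (max(e0, cds_lo), min(e1, cds_hi))
        for e0, e1 in (exon1, exon2, exon3)
        if e1 > cds_lo and e0 < cds_hi)
    return TranscriptModel(
        gene_id=gene_id, transcript_id=f"{gene_id}.t1", chromosome_id=chrom,
        strand=strand, exons=(exon1, exon2, exon3), cds=cds)


def _place_loci(config: SimConfig, rng: np.random.Generator,
                g0: int, g1: int) -> list[int]:
    """Locus start positions within gene +/- 5 kb, >= 100 bp apart."""
    lo = g0 - min(5000, config.flank - 500)
    hi = g1 + min(5000, config.flank - 500)
    positions: list[int] = []
    attempts = 0
    while len(positions) < config.loci_per_gene:
        attempts += 1
        if attempts > 1000:
            raise ValueError("infeasible locus packing within gene territory")
        pos = int(rng.integers(lo, hi - 80))
        if all(abs(pos - p) >= 100 + max(config.base_span_range) for p in positions):
            positions.append(pos)
    return sorted(positions)


def _parent_span(truth_span: int, u: int, config: SimConfig,
                 rng: np.random.Generator) -> int:
    deltas = np.arange(-2, 3)
    d = int(rng.choice(deltas, p=np.asarray(config.expansion_probs)))
    return max(u + 1, truth_span + d * u)


def _noisy_segment(segment: str, rng: np.random.Generator, config: SimConfig,
                   protect_left: int, protect_right: int,
                   chrom: str, offset: int, individual: str,
                   truth: SimTruth) -> str:
    """Apply SNP/indel noise to the unprotected core of a segment."""
    n = len(segment)
    core0 = min(protect_left, n)
    core1 = max(core0, n - protect_right)
    if core1 - core0 <= 0 or (config.snp_rate == 0 and config.indel_rate == 0):
        return segment
    seq = bytearray(segment, "ascii")
    core_len = core1 - core0
    n_snp = rng.binomial(core_len, config.snp_rate)
    if n_snp:
        snp_pos = rng.choice(core_len, size=n_snp, replace=False) + core0
        for p in sorted(snp_pos.tolist()):
            old = seq[p]
            alts = [b for b in _BASES.tolist() if b != old]
            seq[p] = int(rng.choice(alts))
            truth.snp_positions.setdefault(individual, []).append((chrom, offset + p))
    n_indel = rng.binomial(core_len, config.indel_rate)
    if not n_indel:
        return seq.decode("ascii")
    text = seq.decode("ascii")
    indel_pos = sorted((rng.choice(core_len, size=n_indel, replace=False) + core0).tolist(),
                       reverse=True)
    for p in indel_pos:
        size = int(rng.integers(1, config.indel_max + 1))
        if rng.integers(2) == 0 and p + size <= core1:  # deletion
            text = text[:p] + text[p + size :]
            truth.indel_positions.setdefault(individual, []).append((chrom, offset + p, -size))
        else:  # insertion
            ins = "".join(chr(b) for b in rng.choice(_BASES, size=size))
            text = text[:p] + ins + text[p:]
            truth.indel_positions.setdefault(individual, []).append((chrom, offset + p, size))
    return text


def simulate_individuals(
    reference: SimReference, config: SimConfig
) -> dict[str, dict[str, str]]:
    """Six trio consensus genomes; fills truth spans and missing flags.

    Parent alleles are drawn independently per locus; each child copies the
    span of one uniformly chosen parent. N runs replace a locus (plus 5 bp
    on each side) at the configured mask rate, recorded as missing.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = reference.truth
    # allele spans: parents first, children copy one parent per locus
    for locus in truth.loci:
        u = len(locus.motif)
        for fam in FAMILIES:
            father = _parent_span(locus.ref_span, u, config, rng)
            mother = _parent_span(locus.ref_span, u, config, rng)
            child = father if rng.integers(2) == 0 else mother
            locus.spans[f"{fam}_father"] = father
            locus.spans[f"{fam}_mother"] = mother
            locus.spans[f"{fam}_child"] = child
        for ind in INDIVIDUALS:
            locus.missing[ind] = bool(rng.random() < config.n_mask_rate)
    loci_by_chrom: dict[str, list[TruthLocus]] = {}
    for locus in truth.loci:
        loci_by_chrom.setdefault(locus.chromosome_id, []).append(locus)
    genomes: dict[str, dict[str, str]] = {}
    for ind in INDIVIDUALS:
        chroms: dict[str, str] = {}
        for chrom in sorted(reference.sequences):
            ref_seq = reference.sequences[chrom]
            loci = sorted(loci_by_chrom.get(chrom, []), key=lambda t: t.ref_interval)
            pieces: list[str] = []
            prev_end = 0
            prev_was_locus = False
            mask_next = False
            for locus in loci:
                s, e = locus.ref_interval
                seg = _noisy_segment(
                    ref_seq[prev_end:s], rng, config,
                    protect_left=LOCUS_GUARD if prev_was_locus else 0,
                    protect_right=LOCUS_GUARD,
                    chrom=chrom, offset=prev_end, individual=ind, truth=truth)
                if mask_next:
                    seg = "N" * min(5, len(seg)) + seg[5:]
                span = locus.spans[ind]
                mask_next = locus.missing[ind]
                if mask_next:
                    # consensus drop-out obliterates the locus and 5 bp of
                    # flank on each side
                    seg = seg[:-5] + "N" * min(5, len(seg))
                    pieces.append(seg)
                    pieces.append("N" * span)
                else:
                    pieces.append(seg)
                    pieces.append(Motif(locus.motif).array(span))
                prev_end = e
                prev_was_locus = True
            tail = _noisy_segment(
                ref_seq[prev_end:], rng, config,
                protect_left=LOCUS_GUARD if prev_was_locus else 0,
                protect_right=0, chrom=chrom, offset=prev_end,
                individual=ind, truth=truth)
            if mask_next:
                tail = "N" * min(5, len(tail)) + tail[5:]
            pieces.append(tail)
            chroms[chrom] = "".join(pieces)
        genomes[ind] = chroms
    return genomes


def simulate(config: SimConfig) -> tuple[SimReference, dict[str, dict[str, str]]]:
    """Reference plus six individual genomes under one seed."""
    reference = simulate_reference(config)
    genomes = simulate_individuals(reference, config)
    return reference, genomes


@dataclass
class RecoveryReport:
    """Truth-recovery metrics for a full pipeline run."""

    n_truth: int
    n_template: int
    template_sensitivity: float
    template_precision: float
    genotype_total: int
    genotype_exact: int
    missing_agree: int
    missing_truth_only: int
    missing_called_only: int
    deviation_exact: int
    deviation_total: int

    @property
    def genotype_match_rate(self) -> float:
        return self.genotype_exact / self.genotype_total if self.genotype_total else 1.0

    @property
    def missing_exact(self) -> bool:
        return self.missing_truth_only == 0 and self.missing_called_only == 0


def compare_to_truth(
    template: Sequence[TemplateLocus],
    calls: Iterable[LocusCall],
    records: Sequence[PolymorphismRecord],
    truth: SimTruth,
    individuals: Sequence[str] = INDIVIDUALS,
) -> RecoveryReport:
    """Score pipeline output against the generator's truth table.

    A template locus matches a truth locus when they share a chromosome,
    their motifs are rotationally equivalent, and their reference intervals
    overlap. Genotype comparison covers every (matched locus, individual)
    pair whose truth is not masked; masked pairs are scored on the missing
    flag instead.
    """
    call_lookup: dict[tuple[str, str], LocusCall] = {}
    for c in calls:
        call_lookup[(c.locus_id, c.individual_id)] = c
    truth_match: dict[str, str] = {}
    template_matched: set[str] = set()
    for t in truth.loci:
        for locus in template:
            if locus.chromosome_id != t.chromosome_id:
                continue
            if not motifs_equivalent(locus.motif, t.motif):
                continue
            a, b = locus.ref_interval
            if a < t.ref_interval[1] and t.ref_interval[0] < b:
                truth_match[t.locus_id] = locus.locus_id
                template_matched.add(locus.locus_id)
                break
    geno_total = geno_exact = 0
    miss_agree = miss_truth_only = miss_called_only = 0
    dev_exact = dev_total = 0
    rec_lookup = {r.locus_id: r for r in records}
    for t in truth.loci:
        locus_id = truth_match.get(t.locus_id)
        if locus_id is None:
            continue
        for ind in individuals:
            call = call_lookup.get((locus_id, ind))
            truth_missing = t.missing.get(ind, False)
            called_missing = call is None or call.status == "missing"
            if truth_missing:
                if called_missing:
                    miss_agree += 1
                else:
                    miss_truth_only += 1
                continue
            if called_missing:
                miss_called_only += 1
                continue
            geno_total += 1
            if call.span == t.spans[ind]:
                geno_exact += 1
        rec = rec_lookup.get(locus_id)
        truth_spans = [t.spans[i] for i in individuals if not t.missing.get(i, False)]
        truth_spans.append(t.ref_span)  # reference participates in the statistics
        if rec is not None and rec.max_dev is not None and len(truth_spans) >= 2:
            dev_total += 1
            if (rec.max_dev == max_dev(truth_spans)
                    and abs(rec.avg_dev - avg_dev(truth_spans)) < 1e-9):
                dev_exact += 1
    n_truth = len(truth.loci)
    return RecoveryReport(
        n_truth=n_truth,
        n_template=len(template),
        template_sensitivity=len(truth_match) / n_truth if n_truth else 1.0,
        template_precision=(len(template_matched) / len(template)) if template else 1.0,
        genotype_total=geno_total,
        genotype_exact=geno_exact,
        missing_agree=miss_agree,
        missing_truth_only=miss_truth_only,
        missing_called_only=miss_called_only,
        deviation_exact=dev_exact,
        deviation_total=dev_total,
    )


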