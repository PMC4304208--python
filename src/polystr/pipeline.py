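"""End-to-end orchestration of the polymorphic-STR workflow.

For every annotated gene: build the reference context with flanks and
anchors, calibrate each individual's sequence against it, detect STRs in
every calibrated sequence, lift them onto reference coordinates, merge
fragmented segments, union everything into the template profile, re-measure
every template locus in every genome, and finally compute polymorphism
calls, region codes, biomarker classes, summary statistics and reports.
A failure in one gene never aborts the run: the gene is recorded as
calibration_failed in the manifest and all other genes are unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd

from .annotation import (
    AnnotationError,
    Pedigree,
    RegionCode,
    TranscriptModel,
    assign_region,
    classify_biomarker,
)
from .calibration import (
    AlignmentError,
    CalibratedPair,
    CalibrationError,
    CoordMap,
    GeneContext,
    align_global,
    build_gene_context,
    calibrate_sequence,
    reference_pair,
)
from .detector import DetectorConfig
from .io import (
    RunConfig,
    chromosome_summary_frame,
    classification_frame,
    genotype_matrix_frame,
    locus_table_frame,
    manhattan_frame,
    write_reports,
)
from .profiling import (
    LocusCall,
    STRProfile,
    TemplateLocus,
    build_profile,
    build_template,
    call_polymorphisms,
    genotype_locus,
    merge_adjacent,
)
from .statistics import (
    PolymorphismRecord,
    manhattan_points,
    select_candidates,
    summarize_gene_set,
)

logger = logging.getLogger("polystr")

REFERENCE_ID = "reference"

STATUS_OK = "ok"
STATUS_FAILED = "calibration_failed"
STATUS_EXCLUDED = "excluded"


class PipelineError(RuntimeError):
    """Run-level failure: no gene could be calibrated at all."""


class NoMatchError(RuntimeError):
    """A custom query sequence matched no catalogued gene at threshold."""


class AmbiguousMatchError(RuntimeError):
    """A custom query sequence matched several genes equally well."""


@dataclass
class RunManifest:
    """Per-gene status accounting for one pipeline run."""

    statuses: dict[str, str] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.statuses)

    def count(self, status: str) -> int:
        return sum(1 for s in self.statuses.values() if s == status)

    @property
    def success_rate(self) -> float:
        considered = self.total - self.count(STATUS_EXCLUDED)
        return self.count(STATUS_OK) / considered if considered else 0.0


@dataclass
class PipelineResult:
    manifest: RunManifest
    template: list[TemplateLocus]
    calls: list[LocusCall]
    records: list[PolymorphismRecord]
    classifications: dict[str, tuple[frozenset[str], bool]]
    contexts: dict[str, GeneContext]
    individual_order: list[str]
    frames: dict[str, pd.DataFrame] = field(default_factory=dict)
    candidates: list = field(default_factory=list)


def _gene_catalog(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, tuple[str, tuple[int, int], list[TranscriptModel]]]:
    out: dict[str, tuple[str, tuple[int, int], list[TranscriptModel]]] = {}
    for tx in transcripts:
        chrom, iv = tx.chromosome_id, tx.interval
        if tx.gene_id in out:
            old_chrom, old_iv, txs = out[tx.gene_id]
            iv = (min(old_iv[0], iv[0]), max(old_iv[1], iv[1]))
            out[tx.gene_id] = (old_chrom, iv, txs + [tx])
        else:
            out[tx.gene_id] = (chrom, iv, [tx])
    return out


def run_pipeline(
    reference: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    individuals: Mapping[str, Mapping[str, str]],
    pedigree: Optional[Pedigree],
    config: RunConfig = RunConfig(),
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run all workflow stages over every annotated gene.

    ``reference`` and each entry of ``individuals`` map chromosome id to
    sequence. Returns the aggregated result; when ``outdir`` is given all
    report tables are written there as TSV.
    """
    det_config = DetectorConfig(quality=config.quality, min_span=config.min_span)
    catalog = _gene_catalog(transcripts)
    individual_ids = sorted(individuals)
    manifest = RunManifest()
    contexts: dict[str, GeneContext] = {}
    template: list[TemplateLocus] = []
    calls: list[LocusCall] = []
    gene_transcripts: dict[str, list[TranscriptModel]] = {}
    for gene_id in sorted(catalog):
        chrom, gene_iv, txs = catalog[gene_id]
        gene_transcripts[gene_id] = txs
        if chrom in config.excluded_chromosomes:
            manifest.statuses[gene_id] = STATUS_EXCLUDED
            manifest.reasons[gene_id] = f"chromosome {chrom} excluded"
            continue
        if chrom not in reference:
            manifest.statuses[gene_id] = STATUS_FAILED
            manifest.reasons[gene_id] = f"chromosome {chrom} missing from reference"
            continue
        try:
            context = build_gene_context(
                reference[chrom], gene_iv, gene_id, chrom,
                flank=config.flank, anchor=config.anchor)
            contexts[gene_id] = context
            gene_template, gene_calls = _process_gene(
                context, individuals, individual_ids, det_config, config, manifest)
        except (CalibrationError, AlignmentError, ValueError) as exc:
            manifest.statuses[gene_id] = STATUS_FAILED
            manifest.reasons[gene_id] = str(exc)
            logger.warning("gene %s failed calibration: %s", gene_id, exc)
            continue
        manifest.statuses[gene_id] = STATUS_OK
        template.extend(gene_template)
        calls.extend(gene_calls)
    if manifest.total and manifest.count(STATUS_OK) == 0:
        raise PipelineError("no gene was successfully calibrated")
    records = call_polymorphisms(template, calls)
    _annotate_regions(records, gene_transcripts, catalog, config.flank)
    classifications = _classify(records, pedigree) if pedigree else {}
    result = PipelineResult(
        manifest=manifest,
        template=template,
        calls=calls,
        records=records,
        classifications=classifications,
        contexts=contexts,
        individual_order=[REFERENCE_ID, *individual_ids],
    )
    _build_frames(result, catalog, config)
    if outdir is not None:
        write_reports(outdir, **result.frames)
        Path(outdir, "manifest.tsv").write_text(_manifest_tsv(manifest))
        config.to_json(Path(outdir, "run_config.json"))
    return result


def _process_gene(
    context: GeneContext,
    individuals: Mapping[str, Mapping[str, str]],
    individual_ids: Sequence[str],
    det_config: DetectorConfig,
    config: RunConfig,
    manifest: RunManifest,
) -> tuple[list[TemplateLocus], list[LocusCall]]:
    ref_pair = reference_pair(context)
    identity = CoordMap.identity(len(ref_pair.ref_seq))
    pairs: dict[str, tuple[CalibratedPair, CoordMap]] = {
        REFERENCE_ID: (ref_pair, identity)}
    profiles: list[STRProfile] = [merge_adjacent(
        build_profile(ref_pair, identity, det_config, REFERENCE_ID,
                      context.chromosome_id),
        max_gap=config.merge_max_gap)]
    for ind in individual_ids:
        chrom_seq = individuals[ind].get(context.chromosome_id)
        if chrom_seq is None:
            raise CalibrationError(context.gene_id,
                                   f"{ind} lacks chromosome {context.chromosome_id}")
        pair = calibrate_sequence(chrom_seq, context, config.min_identity)
        cmap = align_global(pair.ref_seq, pair.target_seq)
        pairs[ind] = (pair, cmap)
        profiles.append(merge_adjacent(
            build_profile(pair, cmap, det_config, ind, context.chromosome_id),
            max_gap=config.merge_max_gap))
    template = build_template(profiles)
    calls: list[LocusCall] = []
    for locus in template:
        for ind, (pair, cmap) in pairs.items():
            call = genotype_locus(locus, pair, cmap, ind, quality=config.quality)
            if call is None:
                manifest.excluded_pairs.append((locus.locus_id, ind))
                logger.info("locus %s excluded for %s (unmapped window)",
                            locus.locus_id, ind)
            else:
                calls.append(call)
    return template, calls


def _annotate_regions(
    records: Sequence[PolymorphismRecord],
    gene_transcripts: Mapping[str, list[TranscriptModel]],
    catalog: Mapping[str, tuple[str, tuple[int, int], list[TranscriptModel]]],
    flank: int,
) -> None:
    for rec in records:
        txs = gene_transcripts.get(rec.gene_id)
        if not txs or rec.ref_interval is None:
            continue
        _, gene_iv, _ = catalog[rec.gene_id]
        try:
            _, summary = assign_region(rec.ref_interval, txs, gene_iv, flank)
            rec.region_code = int(summary)
        except AnnotationError:
            rec.region_code = None


def _classify(
    records: Sequence[PolymorphismRecord],
    pedigree: Pedigree,
) -> dict[str, tuple[frozenset[str], bool]]:
    out: dict[str, tuple[frozenset[str], bool]] = {}
    family_ids = set(pedigree.members)
    for rec in records:
        if rec.indeterminate or not rec.is_polymorphic:
            continue
        family_calls = {i: rec.calls.get(i) for i in family_ids}
        if any(i not in rec.calls for i in family_ids):
            continue
        out[rec.locus_id] = classify_biomarker(
            family_calls, pedigree, rec.is_polymorphic, rec.max_dev)
    return out


def _build_frames(
    result: PipelineResult,
    catalog: Mapping[str, tuple[str, tuple[int, int], list[TranscriptModel]]],
    config: RunConfig,
) -> None:
    region_codes = {r.locus_id: RegionCode(r.region_code)
                    for r in result.records if r.region_code is not None}
    genes_per_chrom: dict[str, tuple[int, int]] = {}
    gene_lengths: dict[str, int] = {}
    for gene_id, (chrom, iv, _) in catalog.items():
        if chrom in config.excluded_chromosomes:
            continue
        n, length = genes_per_chrom.get(chrom, (0, 0))
        genes_per_chrom[chrom] = (n + 1, length + iv[1] - iv[0])
        gene_lengths[gene_id] = iv[1] - iv[0]
    points = manhattan_points(result.records)
    result.candidates = select_candidates(points, config.manhattan_threshold)
    summary, ratios = summarize_gene_set(result.records, gene_lengths)
    summary_frame = pd.DataFrame([{
        "TLSTR(Mbp)": summary.TLSTR, "TLgene(Mbp)": summary.TLgene,
        "TNgene": summary.TNgene, "TNSTR": summary.TNSTR,
        "TNpSTR": summary.TNpSTR, "TNcSTR": summary.TNcSTR,
        **ratios,
    }])
    result.frames = {
        "genotype_matrix": genotype_matrix_frame(
            result.template, result.calls, result.individual_order, region_codes),
        "gene_set_summary": summary_frame,
        "chromosome_summary": chromosome_summary_frame(result.records, genes_per_chrom),
        "polymorphic_loci": locus_table_frame(
            result.records, result.individual_order, result.calls),
        "classification": classification_frame(
            result.records, result.classifications, result.individual_order),
        "manhattan": manhattan_frame(points),
    }


def _manifest_tsv(manifest: RunManifest) -> str:
    lines = ["gene\tstatus\treason"]
    for gene in sorted(manifest.statuses):
        lines.append(f"{gene}\t{manifest.statuses[gene]}\t"
                     f"{manifest.reasons.get(gene, '')}")
    lines.append(f"#total\t{manifest.total}\t")
    lines.append(f"#ok\t{manifest.count(STATUS_OK)}\t")
    lines.append(f"#failed\t{manifest.count(STATUS_FAILED)}\t")
    lines.append(f"#excluded\t{manifest.count(STATUS_EXCLUDED)}\t")
    lines.append(f"#success_rate\t{manifest.success_rate:.4f}\t")
    return "\n".join(lines) + "\n"


def compare_custom_sequence(
    query_sequence: str,
    result: PipelineResult,
    config: RunConfig = RunConfig(),
    query_id: str = "query",
) -> pd.DataFrame:
    """Genotype a user-supplied sequence against the built template.

    The query must match exactly one catalogued gene context at identity
    >= config.min_identity (computed over a global alignment of the
    calibrated query against the calibrated reference). The query's calls
    are appended as an extra column to the per-locus comparison table of
    that gene.
    """
    best: list[tuple[float, str, CalibratedPair]] = []
    for gene_id in sorted(result.contexts):
        context = result.contexts[gene_id]
        try:
            pair = calibrate_sequence(query_sequence, context, config.min_identity)
        except CalibrationError:
            continue
        dist = edlib.align(pair.target_seq, pair.ref_seq, mode="NW",
                           task="distance")["editDistance"]
        identity = 1.0 - dist / max(len(pair.ref_seq), len(pair.target_seq))
        if identity >= config.min_identity:
            best.append((identity, gene_id, pair))
    if not best:
        raise NoMatchError(
            f"query matches no catalogued gene at identity >= {config.min_identity}")
    best.sort(key=lambda t: (-t[0], t[1]))
    if len(best) > 1 and best[0][0] == best[1][0]:
        raise AmbiguousMatchError(
            f"query matches multiple genes equally well: "
            f"{best[0][1]}, {best[1][1]}")
    _, gene_id, pair = best[0]
    cmap = align_global(pair.ref_seq, pair.target_seq)
    gene_loci = [l for l in result.template if l.gene_id == gene_id]
    query_calls = []
    for locus in gene_loci:
        call = genotype_locus(locus, pair, cmap, query_id, quality=config.quality)
        if call is not None:
            query_calls.append(call)
    order = [*result.individual_order, query_id]
    relevant = [c for c in result.calls
                if any(c.locus_id == l.locus_id for l in gene_loci)]
    return genotype_matrix_frame(gene_loci, relevant + query_calls, order)
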