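"""On-disk formats, report rendering and run configuration.

FASTA reading goes through Biopython (plain or gzipped) with uppercase
normalization; N is allowed, any other non-ACGT character is rejected with
its location. Annotation loads from a GFF3 subset (gene/mRNA/exon/CDS, via
gffutils) or a BED table (6 columns: gene interval only; 12 columns: full
exon/CDS structure); both are normalized to internal 0-based half-open
coordinates. Report writers mirror the published table layouts as CSV/TSV:
a genotype matrix (missing calls rendered "0*"), gene-set and per-chromosome
summaries (the latter sorted by polymorphic STR density, descending), a
polymorphic-locus table sorted by Avg.Dev then Max.Dev, a biomarker
classification table, and a Manhattan TSV. All outputs are deterministic
given identical inputs and configuration.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import gffutils
import pandas as pd
from Bio import SeqIO

from .annotation import REGION_NAMES, RegionCode, TranscriptModel
from .profiling import LocusCall, TemplateLocus
from .repeat_model import format_repeat_number
from .statistics import (
    BP_PER_MBP,
    ManhattanPoint,
    PolymorphismRecord,
    density,
    occurrence_ratio,
    round_half_up,
)

MISSING_MARK = "0*"
_SEQ_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """A malformed input file; the message locates the offending content."""


@dataclass
class RunConfig:
    """All tunable parameters of a full run; JSON round-trip stable."""

    quality: float = 1.0
    min_span: int = 20
    flank: int = 7000
    anchor: int = 500
    min_identity: float = 0.99
    merge_max_gap: int = 10
    manhattan_threshold: float = 6.0
    seed: int = 0
    excluded_chromosomes: tuple[str, ...] = ("Y",)

    def __post_init__(self) -> None:
        if not 0.5 <= self.quality <= 1.0:
            raise ValueError("quality must lie in [0.5, 1.0]")
        if self.min_span < 12 or self.anchor < 0 or self.flank < 0:
            raise ValueError("implausible span/flank/anchor settings")
        if not 0.5 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0.5, 1.0]")
        self.excluded_chromosomes = tuple(self.excluded_chromosomes)

    def to_json(self, path: Optional[Path] = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into {id: sequence}.

    Sequences are uppercased; N is preserved; any other non-ACGTN character
    raises :class:`ParseError` naming the record, position and file line.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _SEQ_ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ParseError(
                    f"{path}: record {rec.id!r} has invalid character "
                    f"{seq[pos]!r} at sequence position {pos + 1} "
                    f"(approx. line {_line_of(path, rec.id, pos)})")
            if rec.id in records:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            records[rec.id] = seq
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _line_of(path: str | Path, record_id: str, seq_pos: int) -> int:
    """Locate the file line holding a sequence position of a record."""
    with _open_text(path) as fh:
        in_record = False
        seen = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if len(line) > 1 else False
                continue
            if in_record:
                seen += len(line.strip())
                if seen > seq_pos:
                    return lineno
    return -1


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    with opener as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[TranscriptModel]:
    """Load transcript models from GFF3 or BED.

    GFF3 coordinates (1-based inclusive) and BED coordinates (0-based
    half-open) are both normalized to internal 0-based half-open. A CDS
    outside its transcript's exons raises :class:`ParseError`.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path: str | Path) -> list[TranscriptModel]:
    try:
        db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:  # gffutils raises a zoo of types
        raise ParseError(f"{path}: not a readable GFF3 file ({exc})") from exc
    models: list[TranscriptModel] = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        gene_ids = tx.attributes.get("Parent", [tx.id])
        exons = tuple(sorted((f.start - 1, f.end)
                             for f in db.children(tx, featuretype="exon")))
        cds = tuple(sorted((f.start - 1, f.end)
                           for f in db.children(tx, featuretype="CDS")))
        if not exons:
            raise ParseError(f"{path}: transcript {tx.id} has no exons")
        try:
            models.append(TranscriptModel(
                gene_id=gene_ids[0], transcript_id=tx.id,
                chromosome_id=tx.seqid, strand=tx.strand,
                exons=exons, cds=cds))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return models


def _read_bed(path: str | Path) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) not in (6, 12):
                raise ParseError(f"{path}:{lineno}: expected 6 or 12 BED columns, "
                                 f"got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if len(parts) == 6:
                exons: tuple[tuple[int, int], ...] = ((start, end),)
                cds: tuple[tuple[int, int], ...] = ()
            else:
                thick0, thick1 = int(parts[6]), int(parts[7])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                if len(sizes) != int(parts[9]) or len(offsets) != int(parts[9]):
                    raise ParseError(f"{path}:{lineno}: blockCount mismatch")
                exons = tuple((start + o, start + o + s)
                              for o, s in zip(offsets, sizes))
                cds = tuple(
                    (max(e0, thick0), min(e1, thick1))
                    for e0, e1 in exons
                    if thick0 < thick1 and e1 > thick0 and e0 < thick1)
            try:
                models.append(TranscriptModel(
                    gene_id=name, transcript_id=f"{name}.t1",
                    chromosome_id=chrom, strand=strand, exons=exons, cds=cds))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as a minimal GFF3 subset (1-based inclusive)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in by_gene:
            txs = by_gene[gene_id]
            g0 = min(t.interval[0] for t in txs)
            g1 = max(t.interval[1] for t in txs)
            chrom, strand = txs[0].chromosome_id, txs[0].strand
            fh.write(f"{chrom}\tpolystr\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t"
                     f"ID={gene_id}\n")
            for t in txs:
                t0, t1 = t.interval
                fh.write(f"{chrom}\tpolystr\tmRNA\t{t0 + 1}\t{t1}\t.\t{strand}\t.\t"
                         f"ID={t.transcript_id};Parent={gene_id}\n")
                for i, (e0, e1) in enumerate(t.exons, 1):
                    fh.write(f"{chrom}\tpolystr\texon\t{e0 + 1}\t{e1}\t.\t{strand}\t.\t"
                             f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n")
                for i, (c0, c1) in enumerate(t.cds, 1):
                    fh.write(f"{chrom}\tpolystr\tCDS\t{c0 + 1}\t{c1}\t.\t{strand}\t0\t"
                             f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n")


def render_alignment(
    ref_window: str,
    individual_windows: Mapping[str, str],
    str_interval: Optional[tuple[int, int]] = None,
    ref_label: str = "reference",
) -> str:
    """Stacked fixed-width alignment of windows around one locus.

    Each individual window is aligned to the reference window and projected
    onto reference columns (deleted columns shown as '-'; insertions are
    not displayed). A '*' marks columns where every displayed sequence
    agrees; N is rendered literally and never matches. When given, the STR
    span is framed with '=' markers on a separate line.
    """
    ref = ref_window.upper()
    rows: dict[str, str] = {}
    for name in individual_windows:
        win = individual_windows[name].upper()
        if win == ref:
            rows[name] = win
            continue
        res = edlib.align(win, ref, mode="NW", task="path")
        out = []
        ti = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=X":
                out.append(win[ti : ti + n])
                ti += n
            elif ch == "D":  # reference-only columns
                out.append("-" * n)
            else:  # insertion in the individual: skipped in the projection
                ti += n
        rows[name] = "".join(out)
    width = max(len(ref_label), *(len(n) for n in rows)) if rows else len(ref_label)
    lines = [f"{ref_label:<{width}}  {ref}"]
    for name in sorted(rows):
        lines.append(f"{name:<{width}}  {rows[name]}")
    stars = "".join(
        "*" if all(r[i] == ref[i] and ref[i] != "N" and r[i] != "N"
                   for r in rows.values()) else " "
        for i in range(len(ref)))
    lines.append(f"{'':<{width}}  {stars}")
    if str_interval is not None:
        a, b = str_interval
        frame = " " * a + "=" * (b - a)
        lines.append(f"{'':<{width}}  {frame[: len(ref)]}")
    return "\n".join(lines) + "\n"


def _fmt_call(call: Optional[LocusCall]) -> str:
    if call is None:
        return ""
    if call.status == "missing":
        return MISSING_MARK
    return format_repeat_number(call.repeat if call.repeat is not None else Fraction(0))


def genotype_matrix_frame(
    template: Sequence[TemplateLocus],
    calls: Iterable[LocusCall],
    individual_order: Sequence[str],
    region_codes: Optional[Mapping[str, RegionCode]] = None,
) -> pd.DataFrame:
    """Genotype matrix: rows = locus/pattern, columns = individuals.

    Repeat numbers are rendered to up to six decimals; missing calls as
    "0*"; loci never measured in an individual stay blank.
    """
    lookup: dict[tuple[str, str], LocusCall] = {}
    for c in calls:
        lookup[(c.locus_id, c.individual_id)] = c
    rows = []
    for locus in template:
        region = ""
        if region_codes and locus.locus_id in region_codes:
            region = REGION_NAMES[region_codes[locus.locus_id]]
        pattern = f"{locus.motif}({region})" if region else str(locus.motif)
        row = {"locus": locus.locus_id, "gene": locus.gene_id, "pattern": pattern}
        for ind in individual_order:
            row[ind] = _fmt_call(lookup.get((locus.locus_id, ind)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["locus", "gene", "pattern", *individual_order])


def chromosome_summary_frame(
    records: Iterable[PolymorphismRecord],
    genes_per_chromosome: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-chromosome counts/ratios, sorted by density descending.

    ``genes_per_chromosome`` maps chromosome id to (gene count, total gene
    length in bp). Lengths are reported in Mbp; density to 3 decimals and
    occurrence ratio to 2 (half-up).
    """
    recs = [r for r in records if not r.indeterminate]
    rows = []
    for chrom in sorted(genes_per_chromosome):
        tn_gene, tl_gene_bp = genes_per_chromosome[chrom]
        sub = [r for r in recs if r.chromosome_id == chrom]
        tn_str = len(sub)
        tn_pstr = sum(1 for r in sub if r.is_polymorphic)
        tl_str = sum(r.span_length for r in sub)
        row = {
            "Chr": chrom,
            "TLSTR(Mbp)": round_half_up(tl_str / BP_PER_MBP, 4),
            "TLgene(Mbp)": round_half_up(tl_gene_bp / BP_PER_MBP, 2),
            "TNgene": tn_gene,
            "TNSTR": tn_str,
            "TNpSTR": tn_pstr,
            "Density": density(tn_pstr, tl_gene_bp / BP_PER_MBP, places=3)
            if tl_gene_bp else float("nan"),
            "OccurrenceRatio": occurrence_ratio(tn_pstr, tn_str) if tn_str else float("nan"),
        }
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["Density", "Chr"], ascending=[False, True],
                                  kind="mergesort").reset_index(drop=True)
    return frame


def locus_table_frame(
    records: Iterable[PolymorphismRecord],
    individual_order: Sequence[str],
    calls: Optional[Iterable[LocusCall]] = None,
) -> pd.DataFrame:
    """Polymorphic-locus table sorted by Avg.Dev then Max.Dev, descending."""
    lookup: dict[tuple[str, str], LocusCall] = {}
    if calls is not None:
        for c in calls:
            lookup[(c.locus_id, c.individual_id)] = c
    rows = []
    for r in records:
        if not r.is_polymorphic:
            continue
        row = {
            "locus": r.locus_id,
            "gene": r.gene_id,
            "chromosome": r.chromosome_id,
            "pattern": str(r.motif),
            "region": int(r.region_code) if r.region_code is not None else "",
        }
        for ind in individual_order:
            if lookup:
                row[ind] = _fmt_call(lookup.get((r.locus_id, ind)))
            else:
                span = r.calls.get(ind)
                row[ind] = MISSING_MARK if span is None else format_repeat_number(
                    Fraction(span, len(r.motif)))
        row["Max.Dev"] = r.max_dev
        row["Avg.Dev"] = round_half_up(r.avg_dev, 6)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["locus", "gene", "chromosome", "pattern",
                                        "region", *individual_order,
                                        "Max.Dev", "Avg.Dev"])
    if not frame.empty:
        frame = frame.sort_values(["Avg.Dev", "Max.Dev", "locus"],
                                  ascending=[False, False, True],
                                  kind="mergesort").reset_index(drop=True)
    return frame


def classification_frame(
    records: Iterable[PolymorphismRecord],
    classifications: Mapping[str, tuple[frozenset[str], bool]],
    individual_order: Sequence[str],
) -> pd.DataFrame:
    """Biomarker table: per-individual calls, type names and SNP '*' flag."""
    rows = []
    for r in records:
        if r.locus_id not in classifications:
            continue
        types, snp = classifications[r.locus_id]
        if not types:
            continue
        row = {
            "locus": r.locus_id,
            "gene": r.gene_id,
            "pattern": str(r.motif),
            "region": int(r.region_code) if r.region_code is not None else "",
        }
        for ind in individual_order:
            span = r.calls.get(ind)
            row[ind] = MISSING_MARK if span is None else format_repeat_number(
                Fraction(span, len(r.motif)))
        row["types"] = "+".join(sorted(types))
        row["snp"] = "*" if snp else ""
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["locus", "gene", "pattern", "region",
                                        *individual_order, "types", "snp"])
    return frame.sort_values("locus", kind="mergesort").reset_index(drop=True) \
        if not frame.empty else frame


def manhattan_frame(points: Iterable[ManhattanPoint]) -> pd.DataFrame:
    rows = [{
        "locus": p.locus_id, "chromosome": p.chromosome_id, "position": p.position,
        "median": p.median, "q1": p.q1, "q3": p.q3,
        "normalized_upper": p.normalized_upper,
        "normalized_lower": p.normalized_lower,
        "normalized_max": p.normalized_max,
        "normalized_min": p.normalized_min,
    } for p in points]
    cols = ["locus", "chromosome", "position", "median", "q1", "q3",
            "normalized_upper", "normalized_lower", "normalized_max", "normalized_min"]
    frame = pd.DataFrame(rows, columns=cols)
    return frame.sort_values(["chromosome", "position"], kind="mergesort")\
        .reset_index(drop=True) if not frame.empty else frame


def write_reports(outdir: str | Path, **frames: pd.DataFrame) -> list[Path]:
    """Write named DataFrames as TSV under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(frames):
        path = outdir / f"{name}.tsv"
        frames[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
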