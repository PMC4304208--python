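"""Published seven-genome survey counts and their recomputed summaries.

The genome-scale survey this package's workflow reproduces analysed one
reference genome plus two sequenced trios (CEU and YRI families: NA12878/
NA12891/NA12892 and NA19238/NA19239/NA19240). Its published outputs include
per-chromosome STR counts, gene-set totals, a forensic (CODIS) marker
genotype table and a disease-gene genotype table. Those printed counts are
inputs here: every derived ratio -- polymorphic STR density per Mbp,
occurrence ratios, conserved:polymorphic fold changes, the gene success
rate, and the conserved/missing tallies of the genotype tables -- is
recomputed from them with this package's statistics routines, serving as an
arithmetic-parity check of the implementation.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .statistics import (
    avg_dev,
    density,
    fold_conserved,
    max_dev,
    occurrence_ratio,
    round_half_up,
)

INDIVIDUAL_COLUMNS = ("Reference", "NA12878", "NA12891", "NA12892",
                      "NA19238", "NA19239", "NA19240")

#: per-chromosome totals: TLSTR (Mbp), TLgene (Mbp), TNgene, TNSTR, TNpSTR
CHROMOSOME_COUNTS: dict[str, tuple[float, float, int, int, int]] = {
    "19": (26.62, 3074.71, 2901, 23255, 2834),
    "20": (9.36, 1668.80, 1311, 9836, 1302),
    "X": (16.62, 2983.31, 2345, 16769, 2000),
    "22": (10.61, 1674.64, 1190, 8716, 1100),
    "13": (8.75, 1977.35, 1213, 9002, 1295),
    "9": (17.93, 3533.43, 2261, 16386, 2163),
    "10": (22.42, 4403.78, 2200, 19231, 2641),
    "21": (6.32, 1226.41, 711, 5145, 731),
    "16": (24.74, 3858.90, 2332, 18462, 2238),
    "6": (23.98, 4997.39, 2896, 21135, 2877),
    "1": (44.11, 8295.52, 5222, 38217, 4624),
    "17": (31.47, 4813.97, 2883, 22240, 2574),
    "8": (26.88, 5590.48, 2337, 19247, 2789),
    "7": (33.00, 6499.22, 2792, 24975, 3189),
    "5": (30.27, 6396.45, 2829, 23459, 3109),
    "4": (27.35, 6111.19, 2477, 20358, 2967),
    "12": (33.25, 6107.63, 2808, 23543, 2925),
    "14": (21.26, 4147.19, 2184, 15323, 1971),
    "2": (44.41, 9299.27, 3970, 33220, 4389),
    "15": (21.84, 4292.70, 2061, 16459, 1976),
    "11": (30.39, 6155.13, 3179, 20975, 2770),
    "18": (14.43, 3121.40, 1103, 9448, 1392),
    "3": (43.39, 9234.03, 3030, 27336, 3463),
}

#: gene-set totals: (TNpSTR, TLgene in Mbp)
GENESET_COUNTS: dict[str, tuple[int, float]] = {
    "homologous_225": (357, 1110.20),
    "codis_10": (31, 88.37),
    "human_unique_492": (477, 280.26),
}

TOTAL_GENES = 56852
FAILED_GENES = 617

#: forensic (CODIS) marker repeat numbers per individual; one row per
#: (marker, repeat pattern). Columns follow INDIVIDUAL_COLUMNS.
CODIS_CALLS: list[tuple[str, str, tuple[float, ...]]] = [
    ("CSF1PO", "AGAT", (13.75, 13.75, 13.75, 13.75, 13.75, 13.75, 13.75)),
    ("D3S1358", "AGAT", (14.25, 13.25, 11.5, 13.25, 14.25, 14.25, 14.25)),
    ("D8S1179", "TATC", (13.75, 13.75, 13.75, 13.5, 13.75, 13.5, 13.75)),
    ("TH01", "AATG", (7.75, 7.75, 7.75, 7.75, 7.75, 7.75, 7.75)),
    ("FGA", "AAAG", (14.75, 14.75, 14.75, 14.75, 14.75, 14.75, 14.75)),
    ("D18S51", "GAAA", (15.5, 15.5, 15.5, 15.5, 15.25, 15.25, 15.25)),
    ("TPOX", "AATG", (8.5, 8.5, 8.5, 8.5, 8.5, 8.5, 8.5)),
    ("vWA", "ACAG", (5.0, 3.75, 4.75, 3.75, 5.0, 5.0, 4.75)),
    ("vWA", "AGAT", (11.5, 11.5, 11.5, 11.5, 11.5, 11.5, 11.5)),
    ("vWA", "TCCA", (12.5, 12.5, 12.5, 12.5, 10.25, 11.5, 10.25)),
    ("D7S820", "GATA", (10.75, 10.75, 10.75, 10.75, 10.75, 12.25, 10.75)),
    ("D16S539", "GATA", (11.0, 11.0, 11.0, 11.0, 11.0, 11.0, 11.0)),
    ("D5S818", "AGAT", (11.75, 11.75, 11.75, 11.75, 11.75, 11.75, 11.75)),
    ("D13S317", "GATA", (11.0, 11.0, 11.0, 11.0, 11.0, 11.0, 11.0)),
    ("D21S11", "TCTG", (6.75, 5.75, 5.75, 6.75, 6.75, 6.75, 6.75)),
]

#: disease-gene repeat numbers per individual (None = missing, "0*").
DISEASE_CALLS: list[tuple[str, str, tuple[Optional[float], ...]]] = [
    ("DMPK", "CTG", (20.666666, 19.0, 20.666666, 17.666666, 11.0, 19.333334, 20.666666)),
    ("ATN1", "CAG", (15.666667, 15.666667, 15.333333, 15.666667, 12.0, 15.666667, 15.666667)),
    ("ATXN1", "CAG", (14.666667, 14.666667, 14.666667, 13.0, 14.666667, 14.666667, 14.666667)),
    ("ATXN1", "CAG#2", (13.333333, 13.333333, 13.333333, 13.333333, 13.0, 13.333333, 13.333333)),
    ("EGFR", "CA", (22.0, 22.0, 22.0, 22.0, 22.0, 21.0, 21.0)),
    ("AR", "CAG", (25.000001, 23.666667, 17.333334, 24.333333, 16.333334, 18.666667, 25.000001)),
    ("HTT", "CAG", (19.666666, 10.666667, 11.333333, 15.666667, None, 18.0, 19.666666)),
    ("ATXN3", "CAG", (8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0)),
    ("FMR1", "GCG", (20.333333, None, 9.666667, 2.666667, 13.666667, None, 10.333333)),
    ("PABPN1", "GCG", (7.0, 3.666667, 7.0, 3.0, None, 7.0, 7.0)),
    ("CACNA1A", "CAG", (13.333333, 13.333333, 2.0, 13.333333, 13.333333, 13.333333, 13.333333)),
    ("CALM1", "AGC", (7.0, 8.333333, 8.333333, 8.333333, 7.0, 8.333333, 7.0)),
    ("ATXN10", "AGAAT", (14.0, 14.0, 14.0, 14.0, 14.0, 14.0, 14.0)),
    ("FXN", "CTT", (6.666667, 6.666667, 6.666667, 6.666667, 6.666667, 6.666667, 6.666667)),
]

#: markers that belong to genes (the remaining three CODIS markers are
#: intergenic segments)
CODIS_MARKERS = ("CSF1PO", "D3S1358", "D8S1179", "TH01", "FGA", "D18S51",
                 "TPOX", "vWA", "D7S820", "D16S539", "D5S818", "D13S317",
                 "D21S11")


def _spans(pattern: str, repeats: tuple[Optional[float], ...]) -> list[Optional[int]]:
    """Repeat numbers back to integer spans in bp."""
    u = len(pattern.split("#")[0])
    return [None if r is None else round(r * u) for r in repeats]


def chromosome_table() -> pd.DataFrame:
    """Per-chromosome summary with density, occurrence ratio and fold.

    Density (TNpSTR/TLgene) and occurrence ratio (TNpSTR/TNSTR, %) are
    recomputed from the raw counts; rows are sorted by density descending.
    """
    rows = []
    for chrom, (tlstr, tlgene, tngene, tnstr, tnpstr) in CHROMOSOME_COUNTS.items():
        rows.append({
            "Chr": chrom,
            "TLSTR(Mbp)": tlstr,
            "TLgene(Mbp)": tlgene,
            "TNgene": tngene,
            "TNSTR": tnstr,
            "TNpSTR": tnpstr,
            "Density": density(tnpstr, tlgene, places=3),
            "OccurrenceRatio": occurrence_ratio(tnpstr, tnstr),
            "Fold": fold_conserved(tnstr, tnpstr),
        })
    frame = pd.DataFrame(rows)
    return frame.sort_values("Density", ascending=False, kind="mergesort")\
        .reset_index(drop=True)


def geneset_densities() -> dict[str, float]:
    """Polymorphic STR density per Mbp for each published gene set."""
    return {name: density(tnp, tl) for name, (tnp, tl) in GENESET_COUNTS.items()}


def mean_conserved_fold(places: int = 2) -> float:
    """Average conserved:polymorphic fold change over all chromosomes."""
    frame = chromosome_table()
    return round_half_up(float(frame["Fold"].mean()), places)


def gene_success_rate(places: int = 2) -> float:
    """Percentage of genes successfully processed in the survey."""
    return round_half_up(100.0 * (TOTAL_GENES - FAILED_GENES) / TOTAL_GENES, places)


def chromosome_split(chrom: str, places: int = 1) -> tuple[float, float]:
    """(polymorphic %, conserved %) of all STRs on one chromosome."""
    _, _, _, tnstr, tnpstr = CHROMOSOME_COUNTS[chrom]
    poly = round_half_up(100.0 * tnpstr / tnstr, places)
    return poly, round_half_up(100.0 - poly, places)


def _conserved(repeats: tuple[Optional[float], ...]) -> bool:
    vals = [r for r in repeats if r is not None]
    return len(set(vals)) == 1


def codis_conserved_counts() -> tuple[int, int]:
    """(conserved markers, conserved pattern rows) in the forensic table.

    A marker counts as conserved when every one of its repeat patterns is
    identical across all seven genomes; pattern rows are counted
    individually (the vWA marker contributes three rows).
    """
    rows_conserved = sum(1 for _, _, reps in CODIS_CALLS if _conserved(reps))
    by_marker: dict[str, bool] = {}
    for marker, _, reps in CODIS_CALLS:
        by_marker[marker] = by_marker.get(marker, True) and _conserved(reps)
    loci_conserved = sum(1 for ok in by_marker.values() if ok)
    return loci_conserved, rows_conserved


def disease_fully_called_genes() -> int:
    """Disease genes with a measurable repeat in all seven genomes."""
    by_gene: dict[str, bool] = {}
    for gene, _, reps in DISEASE_CALLS:
        complete = all(r is not None for r in reps)
        by_gene[gene] = by_gene.get(gene, True) and complete
    return sum(1 for ok in by_gene.values() if ok)


def table_deviations() -> pd.DataFrame:
    """Max.Dev/Avg.Dev in bp recomputed from both genotype tables."""
    rows = []
    for source, table in (("codis", CODIS_CALLS), ("disease", DISEASE_CALLS)):
        for name, pattern, reps in table:
            spans = [s for s in _spans(pattern, reps) if s is not None]
            if len(spans) < 2:
                continue
            rows.append({
                "source": source,
                "name": name,
                "pattern": pattern.split("#")[0],
                "max_dev_bp": max_dev(spans),
                "avg_dev_bp": avg_dev(spans),
            })
    return pd.DataFrame(rows)


def parity_summary() -> dict[str, float]:
    """Every headline number of the survey, recomputed from raw counts."""
    frame = chromosome_table()
    by_chr = frame.set_index("Chr")
    dens = geneset_densities()
    loci_cons, rows_cons = codis_conserved_counts()
    devs = table_deviations()

    def dev_of(name: str, pattern: str) -> float:
        sub = devs[(devs["name"] == name) & (devs["pattern"] == pattern)]
        return float(sub["max_dev_bp"].iloc[0])

    poly1, cons1 = chromosome_split("1")
    return {
        "homologous_gene_density": dens["homologous_225"],
        "codis_gene_density": dens["codis_10"],
        "unique_gene_density": dens["human_unique_492"],
        "chr19_occurrence_pct": float(by_chr.loc["19", "OccurrenceRatio"]),
        "chr20_density": float(by_chr.loc["20", "Density"]),
        "chr3_density": float(by_chr.loc["3", "Density"]),
        "max_occurrence_pct": float(by_chr["OccurrenceRatio"].max()),
        "min_occurrence_pct": float(by_chr["OccurrenceRatio"].min()),
        "chr1_polymorphic_pct": poly1,
        "chr1_conserved_pct": cons1,
        "chr1_fold": round_half_up(float(by_chr.loc["1", "Fold"]), 2),
        "mean_conserved_fold": mean_conserved_fold(),
        "gene_success_rate_pct": gene_success_rate(),
        "codis_conserved_markers": float(loci_cons),
        "codis_conserved_patterns": float(rows_cons),
        "disease_genes_fully_called": float(disease_fully_called_genes()),
        "dmpk_max_dev_bp": dev_of("DMPK", "CTG"),
        "vwa_acag_max_dev_bp": dev_of("vWA", "ACAG"),
    }
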