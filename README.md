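# polystr

Identification of conserved and polymorphic short tandem repeats (STRs)
across personal genome consensus sequences.

STRs — tandem arrays of a 1–6 bp unit — expand and contract through
replication slippage, which makes them both forensic identity markers (the
CODIS panel) and disease loci (e.g. the CTG array in *DMPK*, the CAG arrays
in *HTT* and the ataxins). Given a reference genome, a transcript
annotation, and per-individual consensus sequences (e.g. from trio
sequencing), `polystr` automates the comparison:

1. **Gene context construction** — each annotated gene is extended by
   7,000 bp of flank plus a 500 bp *anchor* on each side of the reference.
2. **Calibration** — both anchors are located in each individual's sequence
   by infix alignment at ≥ 99% identity; the sequence between the inner
   anchor edges is excised, and the anchors are trimmed from the reference
   context as well.
3. **STR discovery** — maximal perfect repeat runs (unit 1–6 bp, span
   ≥ 20 bp) are detected in every calibrated sequence; at quality 0.9 an
   imperfect mode reports runs whose *purity* (1 − edit distance to an
   ideal array / span) is ≥ 0.9.
4. **Coordinate mapping** — each individual is globally aligned to the
   calibrated reference and every detected run is lifted onto reference
   coordinates; fragmented same-motif segments ≤ 10 bp apart are re-merged.
5. **Template union** — records from all genomes (reference included) are
   clustered under rotational motif equivalence and ≥ 1 bp interval
   overlap into a unified *template profile* of repeat loci.
6. **Genotyping & statistics** — every template locus is re-measured in
   every genome with no minimum span (an N-obscured window is reported as
   missing, `0*`). Per locus across n genomes with spans |aᵢ|:

   * `Max.Dev = max|aᵢ| − min|aⱼ|` (bp)
   * `Avg.Dev = Σ_{i<j} | |aᵢ| − |aⱼ| | / C(n,2)` (bp)

   A locus is *polymorphic* when Max.Dev ≥ 1 bp, *conserved* when all spans
   agree. Downstream summaries include polymorphic STR density
   (TNpSTR/TLgene, loci/Mbp), occurrence ratio (TNpSTR/TNSTR, %),
   Manhattan-style normalized variation (quartiles × ±1.25 / median) for
   biomarker candidate selection, region codes (1=Intron … 7=Undefined
   exon), and pedigree-aware biomarker classes (INDIVIDUAL / INHERITANCE /
   GROUP, plus a SNP flag for 1 bp deviations).

A synthetic-data module generates the full study design — one reference and
two father/mother/child trios with planted repeat loci, inheritance,
SNP/indel noise and N-masking — with a truth table, so the entire workflow
is testable without any external data.

## Worked example

Simulate a tiny two-trio dataset (4 genes, 12 planted loci, mild noise) and
run the full workflow:

```
$ polystr simulate --seed 7 --outdir demo --config simcfg.json
wrote synthetic dataset to demo

$ polystr run-all --reference demo/reference.fa --annotation demo/annotation.gff3 \
    --pedigree demo/pedigree.tsv --config runcfg.json --outdir demo/reports \
    --individual demo/F1_father.fa ... --individual demo/F2_child.fa
WARNING polystr: gene G0001 failed calibration: G0001: downstream anchor not found
genes ok 3/4, success rate 75.00%; 9 template loci; 8 polymorphic
```

One gene drew an indel inside its anchor and dropped below the 99%
identity gate, so it is counted as a calibration failure while the other
three genes complete. The genotype matrix renders fractional repeat
numbers per genome, e.g.

```
locus                    gene   pattern             reference F1_child F1_father F1_mother ...
chr1:22557-22588:AATTCG  G0002  AATTCG(Downstream)  5.166667  5.166667 5.166667  3.166667  ...
```

(F1_mother carries a two-unit contraction of this hexamer locus), and the
polymorphic-locus table reports the deviations, with `0*` marking a locus
obscured by N in one genome:

```
locus                   pattern  reference F1_child F1_father F1_mother ... Max.Dev Avg.Dev
chr2:22861-22911:AGCTC  AGCTC    10        11       11        0*        ... 15.0    8.666667
```

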