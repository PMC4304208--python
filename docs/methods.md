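# Methods

## Repeat model

A motif is stored canonically: the unit is reduced to its primitive form
(the shortest string whose repetition reconstructs it) and then rotated to
the lexicographically smallest cyclic rotation, so `GATA`, `ATAG` and
`AGATAGAT` all normalize to `AGAT`. Two units denote the same repeat family
iff their canonical forms are equal ("rotational tolerance"); this absorbs
the phase shifts that point mutations and indels introduce at run
boundaries. Reverse-complement units are deliberately **not** equated:
repeat patterns are strand-specific in forensic marker nomenclature, and
the annotation-driven orientation of each gene fixes the strand at load
time. Repeat numbers are exact rationals span/unit (a 55 bp AGAT array is
13.75 repeats) stored unrounded and rendered to at most six decimals,
half-up, at output time.

## Detection

**Perfect runs** are maximal intervals satisfying `s[k] == s[k+u]`
throughout, found by a vectorized shifted-equality scan per unit length
u ∈ 1..6 with a 20 bp minimum span. N never participates in a run. A run
for a composite unit nested inside a run for a divisor unit is suppressed,
so a homopolymer is reported once rather than at every unit length that
divides it. Ties among overlapping candidates order deterministically by
longer span, then shorter unit, then leftmost start, then motif.

**Purity** of a region against a motif is 1 − (minimum over the motif's
phases of the edit distance between the region and an equally long ideal
tandem array) / region length. Edit distances come from edlib; N inside a
region counts as a mismatch because the ideal array never contains N.

**Imperfect detection** (quality q < 1, typically 0.9) is seed-and-chain:
every maximal perfect fragment (at least one periodicity comparison) is a
chain element, and from each fragment the chain greedily absorbs later
same-motif fragments while the full region's purity stays ≥ q — checking
every reachable end, so a transient dip inside a noisy patch does not stop
the chain. Gaps above 10 bp, or containing N, break chains; a reported
chain must contain a *seed* core of ≥ 2 units; region boundaries coincide
with perfect-core boundaries so trailing noise is never absorbed. At
q = 1.0 the tolerant detector is defined to be exactly the perfect one.
Because boundaries are core-aligned, the detector reports the maximal
qualifying region among core-bounded candidates; an exhaustive
all-sub-intervals enumerator is used as the oracle in tests. The upstream
literature describes imperfect repeat mining by autocorrelation without a
reproducible scoring, so the purity contract above *is* this package's
definition of imperfect detection.

## Calibration and coordinate mapping

Gene contexts extend each gene by flank (7,000 bp) + anchor (500 bp) per
side, clipped at chromosome ends; a clipped anchor shorter than 200 bp
fails calibration (degenerate-input policy). Anchors are located in an
individual's sequence by edlib infix (semi-global) alignment; a hit needs
identity ≥ 0.99 (1 − edits/anchor length), ties resolve to the outermost
position, and the upstream hit must precede the downstream hit. The
calibrated pair is the individual sequence strictly between the inner
anchor edges versus the reference context minus both anchors.

Global alignment of the calibrated pair uses edlib's edit-distance-optimal
path (O(n·d), comfortably fast for ~17 kb near-identical pairs, where a
full affine DP with traceback would need hundreds of millions of cells).
Edit-optimal paths can scatter one indel across nearby blocks on
repetitive sequence, so a refinement pass re-aligns any window where two
gap blocks are separated by ≤ 10 aligned columns with an exact affine-gap
(Gotoh) DP (+1 match, −1 mismatch, −10 gap open, −0.5 gap extend,
EDNAFULL-like), splicing the refined ops back. The test suite audits the
result against an independent exhaustive affine DP oracle on miniature
fixtures.

The resulting CoordMap covers both sequences exactly once with M/I/D
columns. Interval lifting returns the smallest covering interval on the
other coordinate system; positions inside a target-only insertion map to
the insertion's left reference edge, and zero-length intervals map to
zero-length intervals at the corresponding edge. A length ratio outside
[0.5, 2] is rejected before alignment as suspicious input.

## Profiles, template, genotyping

Detected records are lifted onto reference coordinates to form per-genome
profiles. Same-motif records whose reference gap is ≤ 10 bp re-merge when
the merged target region keeps purity ≥ quality − 0.05 (overlapping
records union unconditionally); 10 bp is half the minimum span, small
enough not to chain unrelated loci. The template is the single-linkage
union across all profiles (reference included) linking records with
equivalent motifs and ≥ 1 bp reference overlap — overlap rather than exact
coordinates absorbs the residual ±unit jitter that calibration leaves.

Genotyping re-measures each template locus in each genome inside the locus
interval lifted to that genome and widened by one unit per side, with **no
minimum span** (fractional sub-20 bp calls such as 2.666667 GCG repeats
are legitimate at known loci). A run must contain a full unit and
intersect the lifted interval itself — a stray unit in the window padding
is not a call. When the aligner parks an insertion at a run edge, the run
is extended by pure periodicity beyond the window so expansions are
measured in full. Missing semantics: a window containing N with no
qualifying run is `missing` (rendered `0*`); a clean window with no run is
a genuine zero-length call. Loci with fewer than two non-missing calls are
indeterminate and excluded from all statistics (the deviation statistics
need at least one pair).

## Statistics and classification

Avg.Dev averages absolute span differences over all C(n,2) unordered
pairs, pairwise-complete over non-missing calls (with n adjusted); it is
computed by the sorted-prefix identity and cross-checked against direct
pair enumeration. Density and occurrence ratios round half-up to 4 and 2
decimals. Manhattan points use inclusive linear-interpolation quartiles
(numpy's default); the upper/lower bounds multiply Q3/Q1 by +1.25/−1.25
and all four summaries divide by the median repeat number across genomes —
the signed-factor reading of the normalization, which makes the lower
bound negative and leaves selection to the normalized maximum. Candidate
selection keeps loci with normalized maximum ≥ threshold and is monotone
in the threshold.

Region codes follow the locus midpoint against each transcript
(1=Intron, 2=Upstream, 3=Downstream, 4=5'UTR, 5=Coding, 6=3'UTR,
7=Undefined exon, strand-aware); loci straddling a boundary take the
midpoint's class, and the gene-level summary comes from the longest
transcript. Biomarker classes compare spans exactly: INDIVIDUAL = all six
family members pairwise distinct; INHERITANCE = each child matches a
parent at a polymorphic locus; GROUP = family-constant but
family-distinct; a 1 bp maximum deviation sets the SNP flag. GROUP implies
INHERITANCE by construction, and the reference pseudo-individual
participates in polymorphism statistics but never in family logic.

## Synthetic data

The generator emulates the seven-genome trio design: random uniform-ACGT
chromosomes carry three-exon genes (CDS mid-gene, UTRs derived, strands
alternating) spaced so neighbouring gene contexts never overlap; three
perfect STR arrays per gene are planted inside gene ± 5 kb, ≥ 100 bp
apart, with the flanking base on each side chosen to break the array's
periodicity so every planted run is exactly maximal. Reference spans are
28–60 bp over units 1–6 (mono/di-rich weights). Parents draw per-locus
spans as reference ± {0,1,2} units with probabilities (0.50, 0.30, 0.20
split symmetrically); each child copies one uniformly chosen parent per
locus. Noise defaults: SNPs at 1e-3 (human-like heterozygosity scale),
1–5 bp indels at 1e-4, both kept ≥ 10 bp away from loci; consensus
drop-out masks a locus plus 5 bp of each flank with N at rate 0.02 per
(locus, genome). Everything — spans, missing flags, variant positions — is
recorded in a truth table, and all randomness flows from one seed, giving
byte-identical datasets per seed.

What the generator does not emulate: diploid heterozygosity (one allele
per genome, as in consensus sequences), read-level sequencing error,
stutter noise, non-uniform base composition, and segmental duplication.
Passing recovery tests therefore demonstrates the correctness of the
workflow's bookkeeping — calibration, mapping, union, genotyping — under
realistic indel/SNP displacement, not robustness to raw-read artefacts.

## Problem sizes and numerical choices

Acceptance-level runs use the full stated design — 50 genes, 150 planted
loci, two trios, 7,000/500 bp flanks/anchors — under three regimes
(noise-free, flank SNPs at 0.005, N-masking at 0.05); each completes in a
few seconds. Unit tests use 4–6 gene datasets. The detector oracle runs
200 random 1–2 kb sequences; the deviation oracle 1,000 random call
vectors. Determinism is asserted byte-for-byte on written reports.

Known limitations: anchor location at the 99% identity gate fails honestly
when a gene's anchor accumulates > 1% divergence (elevated SNP regimes
lose a fraction of genes, mirroring the boundary/variation failures any
anchor-based calibration suffers); compound and interrupted repeat
nomenclature is out of scope; and imperfect detection reports core-bounded
regions, so a qualifying interval whose optimal boundary lies strictly
inside a noisy stretch may be reported slightly shorter than the
enumeration optimum.
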