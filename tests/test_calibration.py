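"""Gene contexts, anchor location, global alignment and coordinate liftover."""

import numpy as np
import pytest

from polystr.calibration import (
    AlignmentError,
    AlignScoring,
    CalibrationError,
    CoordMap,
    align_global,
    build_gene_context,
    calibrate_sequence,
    locate_anchors,
    reference_pair,
)

from conftest import random_sequence


# --- exhaustive affine-gap oracle (Gotoh DP) ------------------------------

def affine_optimal_score(a: str, b: str, sc: AlignScoring) -> float:
    """Optimal global affine-gap alignment score by full dynamic programming."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = sc.gap_open + sc.gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = sc.gap_open + sc.gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + sc.gap_open, X[i - 1][j] + sc.gap_extend)
            Y[i][j] = max(M[i][j - 1] + sc.gap_open, Y[i][j - 1] + sc.gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def coordmap_score(cmap: CoordMap, ref: str, target: str, sc: AlignScoring) -> float:
    """Affine score of the alignment a CoordMap encodes."""
    score = 0.0
    rp = tp = 0
    for n, op in cmap.ops:
        if op == "M":
            for k in range(n):
                score += sc.match if ref[rp + k] == target[tp + k] else sc.mismatch
            rp += n
            tp += n
        else:
            score += sc.gap_open + sc.gap_extend * (n - 1)
            if op == "D":
                rp += n
            else:
                tp += n
    return score


# --- gene contexts --------------------------------------------------------

def test_build_gene_context_interval_arithmetic(rng):
    chrom = random_sequence(rng, 30_000)
    ctx = build_gene_context(chrom, (10_000, 12_000), "g", "c",
                             flank=7000, anchor=500)
    assert ctx.context_interval == (2500, 19_500)
    assert ctx.left_anchor_length == 500
    assert ctx.upstream_anchor == chrom[2500:3000]
    assert ctx.downstream_anchor == chrom[19_000:19_500]
    assert not (ctx.truncated_left or ctx.truncated_right)
    assert ctx.calibrated_reference == chrom[3000:19_000]
    assert ctx.calibrated_offset == 3000


def test_build_gene_context_clipping(rng):
    chrom = random_sequence(rng, 30_000)
    ctx = build_gene_context(chrom, (100, 2100), "g", "c")
    assert ctx.truncated_left and not ctx.truncated_right
    assert ctx.context_interval[0] == 0
    assert ctx.left_anchor_length == 0  # flank fully absorbs the clipped side
    with pytest.raises(CalibrationError, match="truncated"):
        locate_anchors(chrom, ctx)


def test_build_gene_context_degenerate(rng):
    chrom = random_sequence(rng, 5000)
    ctx = build_gene_context(chrom, (1000, 2000), flank=0, anchor=0)
    assert ctx.context_interval == (1000, 2000)
    with pytest.raises(ValueError, match="outside chromosome"):
        build_gene_context(chrom, (4000, 6000))


# --- anchors and calibration ----------------------------------------------

@pytest.fixture(scope="module")
def context(rng):
    chrom = random_sequence(np.random.default_rng(42), 40_000)
    return chrom, build_gene_context(chrom, (12_000, 15_000), "g", "c")


def test_anchors_on_exact_copy(context):
    chrom, ctx = context
    individual = ctx.context_sequence
    up, down = locate_anchors(individual, ctx)
    assert up == (0, 500)
    assert down == (len(individual) - 500, len(individual))
    pair = calibrate_sequence(individual, ctx)
    assert pair.target_seq == ctx.calibrated_reference
    assert pair.ref_offset == ctx.calibrated_offset


def test_anchor_shift_with_insertion(context):
    chrom, ctx = context
    seq = ctx.context_sequence
    mid = len(seq) // 2
    individual = seq[:mid] + "ACGTACGTAC" + seq[mid:]  # 10 bp insertion
    up, down = locate_anchors(individual, ctx)
    assert up == (0, 500)
    assert down == (len(seq) - 500 + 10, len(seq) + 10)
    pair = calibrate_sequence(individual, ctx)
    assert len(pair.target_seq) == len(ctx.calibrated_reference) + 10


def test_missing_downstream_anchor(context):
    chrom, ctx = context
    individual = ctx.context_sequence[:-600]
    with pytest.raises(CalibrationError, match="downstream anchor"):
        locate_anchors(individual, ctx)


def test_deletion_shortens_calibrated_target(context):
    chrom, ctx = context
    seq = ctx.context_sequence
    mid = len(seq) // 2
    individual = seq[:mid] + seq[mid + 7:]
    pair = calibrate_sequence(individual, ctx)
    assert len(pair.target_seq) == len(ctx.calibrated_reference) - 7


def test_calibrated_sequences_contain_no_anchor_bases(context):
    """Anchor clipping, checked with sentinel-tagged anchors."""
    chrom, ctx = context
    sentinel_up = "ACGT" * 125
    sentinel_down = "TGCA" * 125
    seq = sentinel_up + ctx.context_sequence[500:-500] + sentinel_down
    ctx2 = build_gene_context(
        seq + random_sequence(np.random.default_rng(1), 1),  # same content
        (7500, len(seq) - 7500), "g2", "c")
    pair = reference_pair(ctx2)
    assert sentinel_up not in pair.ref_seq
    assert sentinel_down not in pair.ref_seq


def test_out_of_order_anchors(context):
    chrom, ctx = context
    # swap the anchor blocks: downstream content before upstream content
    seq = ctx.context_sequence
    individual = seq[-500:] + seq[500:-500] + seq[:500]
    with pytest.raises(CalibrationError, match="out of order"):
        locate_anchors(individual, ctx)


# --- global alignment and coordinate maps ---------------------------------

def test_identity_alignment(rng):
    seq = random_sequence(rng, 400)
    cmap = align_global(seq, seq)
    assert cmap.ops == [(400, "M")]
    assert cmap.map_interval((10, 30)) == (10, 30)


def test_substitution_keeps_identity_coordinates(rng):
    ref = random_sequence(rng, 300)
    target = ref[:150] + ("A" if ref[150] != "A" else "C") + ref[151:]
    cmap = align_global(ref, target)
    assert cmap.ref_len == cmap.target_len == 300
    assert cmap.n_gap_columns == 0
    assert cmap.map_interval((140, 160)) == (140, 160)


def test_deletion_creates_gap_block(rng):
    ref = random_sequence(rng, 400)
    target = ref[:100] + ref[105:]
    cmap = align_global(ref, target)
    assert cmap.ref_len == 400 and cmap.target_len == 395
    d_blocks = [(n, op) for n, op in cmap.ops if op == "D"]
    assert sum(n for n, _ in d_blocks) == 5
    # target positions after the gap map back with the +5 shift
    assert cmap.map_interval((200, 220)) == (205, 225)


def test_alignment_matches_affine_oracle_on_miniatures():
    sc = AlignScoring()
    ref = "ACGTACGTACGTAGGCATCGATCGAAGCTTGCATGCTAACGGTA"
    cases = [
        ref,                               # identical
        ref[:20] + ref[25:],               # 5 bp deletion
        ref[:15] + "T" + ref[15:],         # 1 bp insertion
        ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:],  # substitution
    ]
    for target in cases:
        cmap = align_global(ref, target, sc)
        assert coordmap_score(cmap, ref, target, sc) == pytest.approx(
            affine_optimal_score(ref, target, sc))


def test_length_ratio_guard():
    with pytest.raises(AlignmentError):
        align_global("ACGT" * 100, "ACGT" * 10)
    with pytest.raises(AlignmentError):
        align_global("", "ACGT")


def test_map_interval_insertion_left_edge_rule():
    # 100 M, 5 I (target-only), 300 M
    cmap = CoordMap([(100, "M"), (5, "I"), (300, "M")])
    assert cmap.map_interval((96, 120)) == (96, 115)
    assert cmap.map_interval((100, 105)) == (100, 100)  # pure insertion
    assert cmap.map_interval((50, 50)) == (50, 50)      # zero-length
    with pytest.raises(IndexError):
        cmap.map_interval((400, 500))


def test_roundtrip_on_gap_free_intervals(rng):
    ref = random_sequence(rng, 500)
    target = ref[:200] + ref[205:300] + "ACGTA" + ref[300:]
    cmap = align_global(ref, target)
    # both directions are mutually inverse away from the gaps
    for a, b in [(10, 50), (400, 450)]:
        r = cmap.map_interval((a, b))
        assert cmap.map_ref_interval(r) == (a, b)


def test_coverage_invariant(rng):
    ref = random_sequence(rng, 300)
    target = ref[:100] + "TTTTT" + ref[100:250] + ref[255:]
    cmap = align_global(ref, target)
    assert sum(n for n, op in cmap.ops if op in "MD") == len(ref)
    assert sum(n for n, op in cmap.ops if op in "MI") == len(target)


def test_coordmap_tsv_roundtrip(tmp_path, rng):
    ref = random_sequence(rng, 120)
    target = ref[:40] + ref[45:80] + "GGGG" + ref[80:]
    cmap = align_global(ref, target)
    path = tmp_path / "map.tsv"
    cmap.to_tsv(path)
    assert CoordMap.from_tsv(path) == cmap


def test_calibration_invariance_under_flank_snps(rng):
    """Planted locus interval is stable against <=1% flank SNPs."""
    local = np.random.default_rng(77)
    chrom = random_sequence(local, 40_000)
    locus = "AGAT" * 10
    pos = 20_000
    chrom = chrom[:pos] + locus + chrom[pos + 40:]
    ctx = build_gene_context(chrom, (18_000, 22_000), "g", "c")
    baseline = None
    for trial in range(3):
        seq = list(ctx.context_sequence)
        n_snp = int(len(seq) * 0.01)
        # SNPs land between the anchors (anchor robustness is a separate
        # concern: past ~1% anchor divergence calibration rightly fails)
        core = np.arange(500, len(seq) - 500)
        for p in local.choice(core, size=n_snp, replace=False):
            if abs((p + ctx.context_interval[0]) - pos) < 60:
                continue  # keep the locus and its shoulder intact
            seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
        pair = calibrate_sequence("".join(seq), ctx)
        cmap = align_global(pair.ref_seq, pair.target_seq)
        t0 = pos - pair.ref_offset
        mapped = cmap.map_ref_interval((t0, t0 + 40))
        got = cmap.map_interval(mapped)
        if baseline is None:
            baseline = got
        assert got == baseline == (t0, t0 + 40)
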