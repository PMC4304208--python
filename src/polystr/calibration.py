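"""Reference gene contexts, anchor location, and coordinate liftover.

A gene context is the gene interval extended by ``flank + anchor`` bp on
each side (7000 + 500 by default), clipped at chromosome ends. The
outermost ``anchor`` bp on each side serve as anchors: they are located in
each individual's consensus sequence by infix alignment at >= 99% identity,
the sequence strictly between the two anchor hits is excised ("calibrated"),
the anchors are likewise trimmed from the reference context, and the two
calibrated sequences are globally aligned. The resulting column-level
coordinate map lifts detected repeat intervals from individual coordinates
onto the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import edlib
import numpy as np

DEFAULT_FLANK = 7000
DEFAULT_ANCHOR = 500
DEFAULT_MIN_IDENTITY = 0.99
#: a clipped anchor shorter than this cannot be located reliably
MIN_ANCHOR_LENGTH = 200


class CalibrationError(RuntimeError):
    """A gene region could not be calibrated for an individual."""

    def __init__(self, gene_id: str, reason: str):
        super().__init__(f"{gene_id}: {reason}")
        self.gene_id = gene_id
        self.reason = reason


class AlignmentError(RuntimeError):
    """Global alignment preconditions violated (suspicious input)."""


@dataclass(frozen=True)
class GeneContext:
    """A reference gene with its flanking and anchor segments.

    ``context_interval`` covers the gene plus up to ``flank + anchor`` bp on
    each side on the reference chromosome; truncation flags record clipping
    at chromosome ends.
    """

    gene_id: str
    chromosome_id: str
    gene_interval: tuple[int, int]
    context_interval: tuple[int, int]
    context_sequence: str
    flank: int = DEFAULT_FLANK
    anchor: int = DEFAULT_ANCHOR
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def left_anchor_length(self) -> int:
        ext = self.gene_interval[0] - self.context_interval[0]
        return max(0, min(self.anchor, ext - self.flank))

    @property
    def right_anchor_length(self) -> int:
        ext = self.context_interval[1] - self.gene_interval[1]
        return max(0, min(self.anchor, ext - self.flank))

    @property
    def upstream_anchor(self) -> str:
        return self.context_sequence[: self.left_anchor_length]

    @property
    def downstream_anchor(self) -> str:
        n = self.right_anchor_length
        return self.context_sequence[len(self.context_sequence) - n :]

    @property
    def calibrated_reference(self) -> str:
        """Context sequence with both anchors removed."""
        n = len(self.context_sequence)
        return self.context_sequence[self.left_anchor_length : n - self.right_anchor_length]

    @property
    def calibrated_offset(self) -> int:
        """Chromosome coordinate of the first calibrated-reference base."""
        return self.context_interval[0] + self.left_anchor_length


def build_gene_context(
    reference_chromosome: str,
    gene_interval: tuple[int, int],
    gene_id: str = "gene",
    chromosome_id: str = "chr",
    flank: int = DEFAULT_FLANK,
    anchor: int = DEFAULT_ANCHOR,
) -> GeneContext:
    """Expand a gene interval by ``flank + anchor`` per side, clipped."""
    g0, g1 = gene_interval
    n = len(reference_chromosome)
    if not (0 <= g0 < g1 <= n):
        raise ValueError(f"{gene_id}: gene interval {gene_interval} outside chromosome [0,{n})")
    ext = flank + anchor
    c0 = max(0, g0 - ext)
    c1 = min(n, g1 + ext)
    return GeneContext(
        gene_id=gene_id,
        chromosome_id=chromosome_id,
        gene_interval=(g0, g1),
        context_interval=(c0, c1),
        context_sequence=reference_chromosome[c0:c1].upper(),
        flank=flank,
        anchor=anchor,
        truncated_left=g0 - ext < 0,
        truncated_right=g1 + ext > n,
    )


def _best_hit(anchor_seq: str, individual: str, min_identity: float,
              outermost: str) -> tuple[int, int]:
    """Best infix hit of an anchor in an individual sequence.

    Returns a half-open interval. Ties on score are broken by the outermost
    position ('left' for the upstream anchor, 'right' for the downstream).
    """
    res = edlib.align(anchor_seq, individual, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or 1.0 - dist / len(anchor_seq) < min_identity:
        raise LookupError("no hit at required identity")
    locs = res["locations"]
    if outermost == "left":
        start, end = min(locs, key=lambda le: le[0] if le[0] is not None else 1 << 60)
    else:
        start, end = max(locs, key=lambda le: le[0] if le[0] is not None else -1)
    if start is None:
        start = max(0, end + 1 - len(anchor_seq))
    return (start, end + 1)


def locate_anchors(
    individual_sequence: str,
    context: GeneContext,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate both anchors of a context in an individual sequence.

    Returns ((up_start, up_end), (down_start, down_end)) in individual
    coordinates. Raises :class:`CalibrationError` when an anchor is too
    short (chromosome-end truncation), unfound at ``min_identity``, or the
    hits are out of order.
    """
    if not individual_sequence:
        raise CalibrationError(context.gene_id, "empty individual sequence")
    seq = individual_sequence.upper()
    for side, length in (("upstream", context.left_anchor_length),
                         ("downstream", context.right_anchor_length)):
        if length < MIN_ANCHOR_LENGTH:
            raise CalibrationError(
                context.gene_id, f"{side} anchor truncated to {length} bp")
    try:
        up = _best_hit(context.upstream_anchor, seq, min_identity, "left")
    except LookupError:
        raise CalibrationError(context.gene_id, "upstream anchor not found") from None
    try:
        down = _best_hit(context.downstream_anchor, seq, min_identity, "right")
    except LookupError:
        raise CalibrationError(context.gene_id, "downstream anchor not found") from None
    if up[1] > down[0]:
        raise CalibrationError(context.gene_id, "anchor hits out of order")
    return up, down


@dataclass
class CalibratedPair:
    """A reference/individual sequence pair ready for global alignment.

    ``ref_offset`` maps calibrated-reference position 0 to its chromosome
    coordinate; ``target_offset`` maps calibrated-target position 0 to its
    position in the raw individual sequence.
    """

    gene_id: str
    ref_seq: str
    ref_offset: int
    target_seq: str
    target_offset: int


def calibrate_sequence(
    individual_sequence: str,
    context: GeneContext,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> CalibratedPair:
    """Excise the anchored gene region from an individual sequence.

    The calibrated target runs strictly between the inner edges of the two
    anchor hits; the calibrated reference is the context minus both anchors.
    """
    up, down = locate_anchors(individual_sequence, context, min_identity)
    target = individual_sequence.upper()[up[1] : down[0]]
    if not target:
        raise CalibrationError(context.gene_id, "anchors leave no sequence between them")
    return CalibratedPair(
        gene_id=context.gene_id,
        ref_seq=context.calibrated_reference,
        ref_offset=context.calibrated_offset,
        target_seq=target,
        target_offset=up[1],
    )


def reference_pair(context: GeneContext) -> CalibratedPair:
    """The reference's own calibrated pair (target == reference)."""
    ref = context.calibrated_reference
    return CalibratedPair(
        gene_id=context.gene_id,
        ref_seq=ref,
        ref_offset=context.calibrated_offset,
        target_seq=ref,
        target_offset=context.calibrated_offset,
    )


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring used to audit alignments on small fixtures."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


class CoordMap:
    """Column-level global alignment between a reference and a target.

    Stored as run-length (length, op) pairs with op M (aligned column,
    match or mismatch), I (target-only insertion) or D (target deletion,
    reference-only column). Both sequences are covered exactly once.
    Interval mapping follows the left-edge rule: positions inside a
    target-only insertion map to the insertion's left reference edge.
    """

    def __init__(self, ops: list[tuple[int, str]]):
        self.ops = [(int(n), op) for n, op in ops if n > 0]
        self.ref_len = sum(n for n, op in self.ops if op in "MD")
        self.target_len = sum(n for n, op in self.ops if op in "MI")
        self._t_lo: Optional[np.ndarray] = None
        self._arrays_built = False

    @classmethod
    def identity(cls, length: int) -> "CoordMap":
        return cls([(length, "M")])

    def _build(self) -> None:
        if self._arrays_built:
            return
        t_lo = np.empty(self.target_len + 1, dtype=np.int64)
        t_hi = np.empty(self.target_len + 1, dtype=np.int64)
        r_lo = np.empty(self.ref_len + 1, dtype=np.int64)
        r_hi = np.empty(self.ref_len + 1, dtype=np.int64)
        rp = tp = 0
        for n, op in self.ops:
            if op == "M":
                t_lo[tp : tp + n] = np.arange(rp, rp + n)
                t_hi[tp : tp + n] = np.arange(rp + 1, rp + n + 1)
                r_lo[rp : rp + n] = np.arange(tp, tp + n)
                r_hi[rp : rp + n] = np.arange(tp + 1, tp + n + 1)
                rp += n
                tp += n
            elif op == "I":
                t_lo[tp : tp + n] = rp
                t_hi[tp : tp + n] = rp
                tp += n
            elif op == "D":
                r_lo[rp : rp + n] = tp
                r_hi[rp : rp + n] = tp
                rp += n
            else:  # pragma: no cover - guarded at parse time
                raise ValueError(f"unknown op {op!r}")
        t_lo[self.target_len] = self.ref_len
        t_hi[self.target_len] = self.ref_len
        r_lo[self.ref_len] = self.target_len
        r_hi[self.ref_len] = self.target_len
        self._t_lo, self._t_hi, self._r_lo, self._r_hi = t_lo, t_hi, r_lo, r_hi
        self._arrays_built = True

    def _map(self, interval: tuple[int, int], lo: np.ndarray, hi: np.ndarray,
             src_len: int) -> tuple[int, int]:
        a, b = interval
        if not (0 <= a <= b <= src_len):
            raise IndexError(f"interval {interval} outside mapped range [0,{src_len}]")
        if a == b:
            edge = int(lo[a])
            return (edge, edge)
        out_lo = int(lo[a])
        out_hi = int(hi[b - 1])
        return (out_lo, max(out_lo, out_hi))

    def map_interval(self, target_interval: tuple[int, int]) -> tuple[int, int]:
        """Smallest reference interval covering a target interval."""
        self._build()
        return self._map(target_interval, self._t_lo, self._t_hi, self.target_len)

    def map_ref_interval(self, ref_interval: tuple[int, int]) -> tuple[int, int]:
        """Smallest target interval covering a reference interval."""
        self._build()
        return self._map(ref_interval, self._r_lo, self._r_hi, self.ref_len)

    def columns(self) -> Iterator[tuple[int, int, str]]:
        """Yield (ref_pos, target_pos, op) per alignment column.

        For I columns ref_pos is the left reference edge; for D columns
        target_pos is the left target edge.
        """
        rp = tp = 0
        for n, op in self.ops:
            for _ in range(n):
                yield rp, tp, op
                if op in "MD":
                    rp += 1
                if op in "MI":
                    tp += 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_pos\ttarget_pos\top\n")
            for rp, tp, op in self.columns():
                fh.write(f"{rp}\t{tp}\t{op}\n")

    @classmethod
    def from_tsv(cls, path) -> "CoordMap":
        ops: list[tuple[int, str]] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("ref_pos"):
                raise ValueError("malformed coordinate-map TSV: missing header")
            for line in fh:
                op = line.rstrip("\n").split("\t")[2]
                if ops and ops[-1][1] == op:
                    ops[-1] = (ops[-1][0] + 1, op)
                else:
                    ops.append((1, op))
        return cls(ops)

    @property
    def n_gap_columns(self) -> int:
        return sum(n for n, op in self.ops if op in "ID")

    def __eq__(self, other) -> bool:
        return isinstance(other, CoordMap) and self.ops == other.ops


def _gotoh_ops(a: str, b: str, sc: AlignScoring) -> list[tuple[int, str]]:
    """Optimal affine-gap global alignment of two short segments.

    ``a`` is the reference, ``b`` the target; returns run-length ops with
    D = gap in target (reference-only) and I = gap in reference. Used only
    to refine small windows, so the full O(nm) traceback is affordable.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # consuming a (D)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # consuming b (I)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = sc.gap_open + sc.gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = sc.gap_open + sc.gap_extend * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sc.match if ai == b[j - 1] else sc.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + sc.gap_open, X[i - 1][j] + sc.gap_extend)
            Y[i][j] = max(M[i][j - 1] + sc.gap_open, Y[i][j - 1] + sc.gap_extend)
    # traceback: prefer staying in a gap state (keeps gaps contiguous)
    i, j = n, m
    state = max((M[n][m], "M"), (X[n][m], "D"), (Y[n][m], "I"))[1]
    rev: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            rev.extend("I" * j)
            break
        if j == 0:
            rev.extend("D" * i)
            break
        if state == "M":
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            target_val = M[i][j] - s
            rev.append("M")
            if X[i - 1][j - 1] == target_val:
                state = "D"
            elif Y[i - 1][j - 1] == target_val:
                state = "I"
            else:
                state = "M"
            i, j = i - 1, j - 1
        elif state == "D":
            rev.append("D")
            if X[i - 1][j] + sc.gap_extend == X[i][j]:
                state = "D"
            else:
                state = "M"
            i -= 1
        else:
            rev.append("I")
            if Y[i][j - 1] + sc.gap_extend == Y[i][j]:
                state = "I"
            else:
                state = "M"
            j -= 1
    ops: list[tuple[int, str]] = []
    for op in reversed(rev):
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + 1, op)
        else:
            ops.append((1, op))
    return ops


#: gap blocks separated by at most this many aligned columns are re-aligned
_REFINE_SEPARATION = 10
_REFINE_PAD = 10
_REFINE_MAX_WINDOW = 400


def _refine_gaps(ops: list[tuple[int, str]], ref: str, target: str,
                 sc: AlignScoring) -> list[tuple[int, str]]:
    """Re-align windows where an edit-optimal path split a gap.

    An edit-distance aligner may scatter a long indel across several blocks
    on repetitive sequence; affine scoring prefers one contiguous gap. Any
    two gap blocks separated by a short match run are re-aligned locally
    with the affine-gap DP and the refined ops spliced back in.
    """
    # annotate blocks with their ref/target start offsets
    blocks: list[tuple[int, str, int, int]] = []
    rp = tp = 0
    for n, op in ops:
        blocks.append((n, op, rp, tp))
        if op in "MD":
            rp += n
        if op in "MI":
            tp += n
    out: list[tuple[int, str]] = []
    i = 0
    while i < len(blocks):
        n, op, brp, btp = blocks[i]
        if op == "M":
            out.append((n, op))
            i += 1
            continue
        # find a cluster of gap blocks with short M separations
        j = i
        while (j + 2 < len(blocks)
               and blocks[j + 1][1] == "M" and blocks[j + 1][0] <= _REFINE_SEPARATION
               and blocks[j + 2][1] != "M"):
            j += 2
        if j == i:
            out.append((n, op))
            i += 1
            continue
        last = blocks[j]
        r0, t0 = brp, btp
        r1 = last[2] + (last[0] if last[1] in "MD" else 0)
        t1 = last[3] + (last[0] if last[1] in "MI" else 0)
        # pad into the flanking matches for context
        pad0 = min(_REFINE_PAD, out[-1][0] if out and out[-1][1] == "M" else 0)
        nxt_m = blocks[j + 1][0] if j + 1 < len(blocks) and blocks[j + 1][1] == "M" else 0
        pad1 = min(_REFINE_PAD, nxt_m)
        window_ref = ref[r0 - pad0 : r1 + pad1]
        window_tgt = target[t0 - pad0 : t1 + pad1]
        if len(window_ref) + len(window_tgt) > _REFINE_MAX_WINDOW:
            out.extend((bn, bop) for bn, bop, _, _ in blocks[i : j + 1])
            i = j + 1
            continue
        if pad0:
            out[-1] = (out[-1][0] - pad0, "M")
            if out[-1][0] == 0:
                out.pop()
        refined = _gotoh_ops(window_ref, window_tgt, sc)
        for bn, bop in refined:
            if out and out[-1][1] == bop:
                out[-1] = (out[-1][0] + bn, bop)
            else:
                out.append((bn, bop))
        if pad1:
            blocks[j + 1] = (nxt_m - pad1, "M", 0, 0)
            if blocks[j + 1][0] == 0:
                j += 1
        i = j + 1
    merged: list[tuple[int, str]] = []
    for n, op in out:
        if n <= 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return merged


def align_global(
    ref_calibrated: str,
    target_calibrated: str,
    scoring: AlignScoring = AlignScoring(),
) -> CoordMap:
    """End-to-end global alignment of a calibrated pair.

    An edit-distance-optimal aligner produces the path; windows where that
    path scatters an indel across nearby blocks are then re-aligned with an
    exact affine-gap DP, so gaps come out contiguous the way an affine
    aligner (and the test-suite DP oracle) places them. A length ratio
    outside [0.5, 2] is rejected as suspicious input.
    """
    if not ref_calibrated or not target_calibrated:
        raise AlignmentError("cannot globally align an empty sequence")
    ratio = len(target_calibrated) / len(ref_calibrated)
    if not 0.5 <= ratio <= 2.0:
        raise AlignmentError(
            f"length ratio {ratio:.2f} outside [0.5, 2]; inputs look unrelated")
    res = edlib.align(target_calibrated.upper(), ref_calibrated.upper(),
                      mode="NW", task="path")
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            op = {"=": "M", "X": "M", "I": "I", "D": "D"}[ch]
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + n, op)
            else:
                ops.append((n, op))
    if sum(1 for _, op in ops if op != "M") > 1:
        ops = _refine_gaps(ops, ref_calibrated.upper(), target_calibrated.upper(),
                           scoring)
    return CoordMap(ops)
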