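"""Core domain types and motif algebra for short tandem repeats (STRs).

An STR motif is a repeat unit of 1-6 nucleotides. Because a tandem array can
be read starting at any phase ("GATA" arrays are the same loci as "AGAT"
arrays), motifs are stored in a canonical form: the lexicographically
smallest rotation of the primitive (non-self-repeating) unit. Two raw units
describe the same repeat family iff their canonical forms are equal
("rotational tolerance"). Reverse-complement units are deliberately NOT
equated: repeat patterns are reported strand-specifically, matching forensic
marker naming conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional

MAX_UNIT_LENGTH = 6
_ALPHABET = frozenset("ACGT")


class MotifError(ValueError):
    """Raised for repeat units that violate the motif contract."""


def _primitive(unit: str) -> str:
    """Smallest prefix of ``unit`` whose repetition reconstructs it."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return unit[:p]
    return unit  # unreachable: p == n always matches


def _min_rotation(unit: str) -> str:
    doubled = unit + unit
    return min(doubled[i : i + len(unit)] for i in range(len(unit)))


@dataclass(frozen=True, order=True)
class Motif:
    """A canonical, primitive repeat unit over {A,C,G,T}, length 1-6.

    Construct via :func:`canonical_motif`; direct construction validates the
    invariants but performs no normalization.
    """

    unit: str

    def __post_init__(self) -> None:
        u = self.unit
        if not u or set(u) - _ALPHABET:
            raise MotifError(f"motif unit must be non-empty over ACGT, got {u!r}")
        if len(u) > MAX_UNIT_LENGTH:
            raise MotifError(f"motif unit longer than {MAX_UNIT_LENGTH} bp: {u!r}")
        if _primitive(u) != u:
            raise MotifError(f"motif unit is not primitive: {u!r}")
        if _min_rotation(u) != u:
            raise MotifError(f"motif unit is not the canonical rotation: {u!r}")

    def __len__(self) -> int:
        return len(self.unit)

    def __str__(self) -> str:
        return self.unit

    def rotation(self, phase: int) -> str:
        """The unit as observed when reading starts ``phase`` bases in."""
        phase %= len(self.unit)
        return self.unit[phase:] + self.unit[:phase]

    def array(self, length: int, phase: int = 0) -> str:
        """An ideal tandem array of ``length`` bp starting at ``phase``."""
        rot = self.rotation(phase)
        reps = length // len(rot) + 2
        return (rot * reps)[:length]


def canonical_motif(raw_unit: str) -> Motif:
    """Canonicalize a raw repeat-unit string.

    Reduces the unit to its primitive form, then takes the lexicographically
    smallest cyclic rotation. Idempotent. Raises :class:`MotifError` for
    non-ACGT characters or primitive units longer than 6 bp.
    """
    unit = raw_unit.upper()
    if not unit:
        raise MotifError("empty repeat unit")
    if set(unit) - _ALPHABET:
        raise MotifError(f"repeat unit contains non-ACGT characters: {raw_unit!r}")
    prim = _primitive(unit)
    if len(prim) > MAX_UNIT_LENGTH:
        raise MotifError(f"primitive unit longer than {MAX_UNIT_LENGTH} bp: {raw_unit!r}")
    return Motif(_min_rotation(prim))


def motifs_equivalent(a: str | Motif, b: str | Motif) -> bool:
    """True iff the two units are rotations of the same primitive motif."""
    ca = a if isinstance(a, Motif) else canonical_motif(a)
    cb = b if isinstance(b, Motif) else canonical_motif(b)
    return ca.unit == cb.unit


def observed_phase(observed_unit: str, motif: Motif) -> int:
    """Rotation offset such that ``motif.rotation(phase) == observed_unit``."""
    obs = observed_unit.upper()
    if len(obs) != len(motif):
        raise MotifError("observed unit length differs from motif length")
    doubled = motif.unit + motif.unit
    idx = doubled.find(obs)
    if idx < 0 or idx >= len(motif):
        raise MotifError(f"{observed_unit!r} is not a rotation of {motif.unit!r}")
    return idx


def repeat_number(span: int, unit_length: int) -> Fraction:
    """Fractional repeat count: span in bp divided by unit length.

    Stored exactly as a rational; use :func:`format_repeat_number` for the
    tabular rendering (up to six decimal places, trailing zeros trimmed).
    """
    if unit_length <= 0 or unit_length > MAX_UNIT_LENGTH:
        raise ValueError(f"unit length must be in 1..{MAX_UNIT_LENGTH}, got {unit_length}")
    if span < 0:
        raise ValueError(f"span must be non-negative, got {span}")
    return Fraction(span, unit_length)


def format_repeat_number(value: Fraction | float, places: int = 6) -> str:
    """Render a repeat number with up to ``places`` decimals, half-up."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = dec.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP)
    text = format(q.normalize(), "f")
    return text


@dataclass
class STRRecord:
    """One detected repeat run.

    Coordinates are 0-based half-open in the *target* sequence the detector
    ran on; ``ref_start``/``ref_end`` are filled after coordinate mapping and
    live on the reference coordinate system.
    """

    sequence_id: str
    start: int
    end: int
    motif: Motif
    observed_phase: int = 0
    purity: float = 1.0
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("STRRecord span must be >= 1 bp")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        if self.ref_start is not None and self.ref_end is not None:
            if self.ref_end < self.ref_start:
                raise ValueError("ref interval must be non-negative")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def repeat_number(self) -> Fraction:
        return repeat_number(self.span, self.unit_length)

    @property
    def ref_interval(self) -> tuple[int, int]:
        if self.ref_start is None or self.ref_end is None:
            raise ValueError("reference coordinates not yet mapped")
        return (self.ref_start, self.ref_end)


@dataclass
class StatsSummary:
    """Aggregate counts for a gene set (lengths in Mbp, counts absolute)."""

    TLSTR: float = 0.0
    TLgene: float = 0.0
    TNgene: int = 0
    TNSTR: int = 0
    TNpSTR: int = 0
    TNcSTR: int = 0

    def __post_init__(self) -> None:
        if min(self.TNgene, self.TNSTR, self.TNpSTR, self.TNcSTR) < 0:
            raise ValueError("counts must be non-negative")
        if self.TNpSTR + self.TNcSTR != self.TNSTR:
            raise ValueError("TNpSTR + TNcSTR must equal TNSTR")
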