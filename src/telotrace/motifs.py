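"""Telomere repeat units and their rotation/strand equivalence semantics.

A telomere motif such as ``TTAGG`` is a circular word: any rotation of the
unit, on either strand, denotes the same repeat. Identity is therefore the
equivalence class under rotation and reverse complement, represented by the
lexicographically minimal rotation over both strands (``canonical_form``).
For display we follow the field convention of writing the G-rich strand
rotation that begins with the longest run of T (``TTAGG``, ``TTAGGTTGGGG``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N is self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(unit: str) -> list[str]:
    """All rotations of ``unit`` in order of rotation index."""
    doubled = unit + unit
    return [doubled[i : i + len(unit)] for i in range(len(unit))]


def primitive_unit(unit: str) -> str:
    """Smallest unit whose tandem repetition equals ``unit``.

    ``TTAGGTTAGG`` reduces to ``TTAGG``; a primitive unit is returned as is.
    """
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return unit[:d]
    return unit


def canonical_form(unit: str) -> str:
    """Rotation/strand invariant representative: the lexicographically
    minimal rotation over the unit and its reverse complement."""
    u = primitive_unit(unit.upper())
    return min(min(rotations(u)), min(rotations(revcomp(u))))


def _leading_t_run(s: str) -> int:
    n = 0
    for c in s:
        if c != "T":
            break
        n += 1
    return n


def display_form(unit: str) -> str:
    """Field-convention display: the G-rich strand rotation beginning with
    the longest T-run (ties broken lexicographically)."""
    u = primitive_unit(unit.upper())
    rc = revcomp(u)
    # G-rich strand = the strand with more G; tie falls back to fewer C.
    if u.count("G") > rc.count("G"):
        strand = u
    elif rc.count("G") > u.count("G"):
        strand = rc
    else:
        strand = min(u, rc)
    rots = rotations(strand)
    best = max(rots, key=lambda r: (_leading_t_run(r), [-ord(c) for c in r]))
    # max with negated ordinals == longest T-run then lexicographically least
    return best


@dataclass(frozen=True)
class TelomereMotif:
    """A telomere repeat unit with rotation/strand equivalence semantics."""

    unit: str
    canonical: str = field(init=False)

    def __post_init__(self) -> None:
        unit = self.unit.upper()
        if not unit or not set(unit) <= DNA_ALPHABET:
            raise ValueError(f"telomere motif {self.unit!r} contains non-ACGT characters")
        unit = primitive_unit(unit)
        if not 3 <= len(unit) <= 25:
            raise ValueError(
                f"telomere motif {self.unit!r}: primitive unit length {len(unit)} outside [3, 25]"
            )
        object.__setattr__(self, "unit", unit)
        object.__setattr__(self, "canonical", canonical_form(unit))

    @property
    def length(self) -> int:
        return len(self.unit)

    @property
    def display(self) -> str:
        return display_form(self.unit)

    @property
    def g_strand(self) -> str:
        """G-rich strand unit in display rotation."""
        return self.display

    @property
    def c_strand(self) -> str:
        """C-rich strand unit (reverse complement of the display form)."""
        return revcomp(self.display)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, TelomereMotif):
            return self.canonical == other.canonical
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.canonical)


def as_motif(motif: "TelomereMotif | str") -> TelomereMotif:
    return motif if isinstance(motif, TelomereMotif) else TelomereMotif(motif)
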