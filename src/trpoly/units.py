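"""Canonical repeat-unit classes.

A tandem-repeat unit is only defined up to cyclic rotation and strand:
reading the same locus from a different phase or from the opposite strand
yields a rotated or reverse-complemented unit (CAG ~ AGC ~ GCA ~ CTG ~ TGC
~ GCT).  All units equivalent under these operations form one *canonical
class*, identified by the lexicographically smallest member.  Triplet
repeats fall into exactly 10 non-homopolymer classes.

Units whose minimal period divides their length ("CACA", "AAA") are
reduced to the minimal-period unit first, so homopolymers of any length
collapse to the single-base class of their base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Display names the field uses for the ten triplet classes (and the
#: quintuplet disease class), keyed by canonical representative.
DISPLAY_NAMES = {
    "AAC": "AAC",
    "ACC": "CAC",
    "AGG": "CCT",
    "AAG": "CTT",
    "ATC": "GAT",
    "ACT": "GTA",
    "ACG": "GTC",
    "AAT": "TAA",
    "AGC": "CAG",
    "CCG": "GGC",
    "AAAAT": "AAAAT",
}


class InvalidUnitError(ValueError):
    """Raised for an empty unit or one with non-ACGT characters."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CanonicalUnit:
    """A rotation/reverse-complement equivalence class of repeat units."""

    representative: str
    members: frozenset[str] = field(repr=False)
    unit_len: int

    @property
    def display_name(self) -> str:
        """The name the literature prints for this class, if conventional."""
        return DISPLAY_NAMES.get(self.representative, self.representative)

    def __contains__(self, unit: str) -> bool:
        return unit in self.members

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.representative


def _validate(unit: str) -> None:
    if not unit:
        raise InvalidUnitError("repeat unit must be non-empty")
    if set(unit) - set("ACGT"):
        raise InvalidUnitError(f"repeat unit {unit!r} contains non-ACGT characters")


def minimal_period(unit: str) -> int:
    """Smallest p dividing len(unit) such that unit is (unit[:p]) repeated."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n  # unreachable: p == n always matches


def _rotations(unit: str) -> set[str]:
    return {unit[i:] + unit[:i] for i in range(len(unit))}


@lru_cache(maxsize=65536)
def canonical_unit(unit: str) -> CanonicalUnit:
    """Return the canonical class containing ``unit``.

    The class is stable under every rotation of the unit and of its
    reverse complement.  ``unit`` is first reduced to its minimal period,
    so "AAAA" yields the length-1 class of A.

    Raises
    ------
    InvalidUnitError
        If the unit is empty or contains characters outside A/C/G/T.
    """
    _validate(unit)
    unit = unit[: minimal_period(unit)]
    members = _rotations(unit) | _rotations(reverse_complement(unit))
    return CanonicalUnit(
        representative=min(members),
        members=frozenset(members),
        unit_len=len(unit),
    )


def enumerate_unit_classes(k: int) -> list[CanonicalUnit]:
    """All canonical classes of units whose minimal period is exactly ``k``.

    For k > 1 this excludes homopolymers and any unit reducible to a
    shorter period; for k = 1 it returns the two homopolymer classes
    ({A,T} and {C,G}).  Ordered by representative.
    """
    if k < 1:
        raise ValueError(f"unit length must be >= 1, got {k}")
    seen: dict[str, CanonicalUnit] = {}
    for idx in range(4**k):
        unit, m = [], idx
        for _ in range(k):
            unit.append("ACGT"[m % 4])
            m //= 4
        s = "".join(unit)
        if minimal_period(s) != k:
            continue
        cls = canonical_unit(s)
        seen.setdefault(cls.representative, cls)
    return [seen[r] for r in sorted(seen)]
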