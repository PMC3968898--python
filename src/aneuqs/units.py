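"""Chromosome units and karyotypes (chromosomal master sequences).

A cell's chromosome content is modelled as an integer copy-number vector over
a fixed, declared set of *chromosome units* — whole chromosomes, or arms and
fragments declared up front.  The copy-number vector is the *chromosomal
master sequence* of the aneuploid quasispecies model; its length

    c = sum of the copy numbers over all units

counts physically distinct chromosome copies, not unit types (a diploid human
karyotype over 23 whole-chromosome units has c = 46).  The unit set is frozen
at configuration time: fragmentation events that would create new units
mid-simulation are out of scope and must instead be declared as arm or
fragment units from the start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChromosomeUnit",
    "Karyotype",
    "StateSpaceCapError",
    "DEFAULT_SPACE_CAP",
    "sequence_length",
    "total_dna_content",
    "concatenate",
    "enumerate_karyotype_space",
    "diploid",
    "validate_unit_set",
]

#: Maximum number of states ``enumerate_karyotype_space`` will materialize.
DEFAULT_SPACE_CAP = 200_000


class StateSpaceCapError(ValueError):
    """Raised when a requested karyotype state space exceeds the cap."""


@dataclass(frozen=True)
class ChromosomeUnit:
    """A whole chromosome, arm, or fragment tracked as one unit.

    Parameters
    ----------
    unit_id
        Short unique label, e.g. ``"chr1"`` or ``"chr1p"``.
    length
        Physical length in base pairs, or a dimensionless weight of 1.0 when
        only copy counts matter.  Must be positive.
    """

    unit_id: str
    length: float = 1.0

    def __post_init__(self) -> None:
        if not self.unit_id:
            raise ValueError("unit_id must be a non-empty string")
        if not (self.length > 0):
            raise ValueError(f"unit length must be > 0, got {self.length!r}")


@dataclass(frozen=True)
class Karyotype:
    """Integer copy-number vector over a declared unit set.

    All entries are non-negative; zero copies of a unit (nullisomy) is
    representable — whether it is viable is decided by the fitness model,
    not here.
    """

    copies: tuple[int, ...]

    def __post_init__(self) -> None:
        for i, c in enumerate(self.copies):
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
                raise TypeError(f"copy number at unit {i} is not an integer: {c!r}")
            if c < 0:
                raise ValueError(f"copy number at unit {i} is negative: {c}")
        object.__setattr__(self, "copies", tuple(int(c) for c in self.copies))

    @classmethod
    def from_iterable(cls, copies: Iterable[int]) -> "Karyotype":
        return cls(tuple(int(c) for c in copies))

    @property
    def n_units(self) -> int:
        return len(self.copies)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.copies, dtype=np.int64)


def sequence_length(k: Karyotype) -> int:
    """Chromosomal master-sequence length c: total copies over all units."""
    return int(sum(k.copies))


def total_dna_content(k: Karyotype, units: Sequence[ChromosomeUnit]) -> float:
    """Copy-number-weighted total DNA content, Σ_u copies[u] × length[u]."""
    if len(units) != k.n_units:
        raise ValueError(
            f"unit set has {len(units)} units but karyotype has {k.n_units}"
        )
    return float(sum(c * u.length for c, u in zip(k.copies, units)))


def concatenate(a: Karyotype, b: Karyotype) -> Karyotype:
    """Join two karyotypes over disjoint unit sets into one."""
    return Karyotype(a.copies + b.copies)


def diploid(n_units: int) -> Karyotype:
    """The diploid karyotype (two copies of every unit)."""
    return Karyotype((2,) * n_units)


def enumerate_karyotype_space(
    n_units: int, max_copy: int, cap: int = DEFAULT_SPACE_CAP
) -> list[Karyotype]:
    """All copy-number vectors in {0..max_copy}^n_units, lexicographic order.

    The order is deterministic (last unit varies fastest).  Spaces larger
    than ``cap`` raise :class:`StateSpaceCapError`; for large total copy
    numbers use the collapsed copy-number-class space instead — a single
    aggregate unit whose state is the total copy count,
    ``enumerate_karyotype_space(1, max_copy)``.
    """
    if n_units < 1 or max_copy < 1:
        raise ValueError("n_units and max_copy must be positive")
    size = (max_copy + 1) ** n_units
    if size > cap:
        raise StateSpaceCapError(
            f"karyotype space has {size} states (> cap {cap}); use the "
            "collapsed copy-number-class approximation (a single aggregate "
            "unit over total copy number) for large spaces"
        )
    return [Karyotype(t) for t in itertools.product(range(max_copy + 1), repeat=n_units)]


def validate_unit_set(units: Sequence[ChromosomeUnit]) -> None:
    """Check unit ids are unique; raise ValueError otherwise."""
    seen: set[str] = set()
    for u in units:
        if u.unit_id in seen:
            raise ValueError(f"duplicate unit_id {u.unit_id!r}")
        seen.add(u.unit_id)
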