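"""Fitness landscapes over karyotype space and population aggregates.

Each karyotype state k carries a growth rate A_k ≥ 0 and a death rate
D_k ≥ 0; the excess production is E_k = A_k − D_k.  A population state is a
frequency vector x on the simplex over the same state space.  The module
also computes the master sequence's *superiority*

    σ̄_m = A_m / (D_m + Ē_{k≠m}),

the relative-fitness index that enters the error-threshold inequality.  The
competitor mean excess production Ē_{k≠m} is normalized by the competitors'
total frequency (Σ_{k≠m} E_k x_k / Σ_{k≠m} x_k), so σ̄_m stays finite and
well-defined as competitors become rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import Karyotype

__all__ = [
    "FitnessAssignment",
    "PopulationState",
    "single_peak_landscape",
    "mean_excess_production",
    "superiority",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class FitnessAssignment:
    """Growth rates A, death rates D, and derived excess E = A − D per state."""

    A: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if A.shape != D.shape or A.ndim != 1:
            raise ValueError(f"A and D must be 1-d and conformable: {A.shape} vs {D.shape}")
        if (A < 0).any() or (D < 0).any():
            raise ValueError("growth and death rates must be non-negative")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "D", D)

    @property
    def E_excess(self) -> np.ndarray:
        return self.A - self.D

    @property
    def n_states(self) -> int:
        return self.A.size


@dataclass(frozen=True)
class PopulationState:
    """Relative-frequency vector on the simplex over the state space."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1:
            raise ValueError("x must be a 1-d vector")
        if (x < -_SIMPLEX_TOL).any():
            raise ValueError("frequencies must be non-negative")
        if abs(x.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"frequencies must sum to 1 (got {x.sum():.12g})")
        object.__setattr__(self, "x", x)


def single_peak_landscape(
    space: Sequence[Karyotype],
    master: Karyotype,
    A_master: float,
    A_mutant: float,
    D_uniform: float = 0.0,
    lethal_on_nullisomy: bool = True,
) -> FitnessAssignment:
    """Single-peak landscape: A_master at the master state, A_mutant elsewhere.

    A single copy-number change can have a large phenotypic effect, so the
    fitness distribution is modelled as sharply peaked at the master
    karyotype.  With ``lethal_on_nullisomy`` (default on), any state missing
    all copies of some unit gets A = 0: losing every copy of an essential
    chromosome cannot yield a viable cell.  Death rate is uniform.
    """
    if not (A_master > A_mutant >= 0):
        raise ValueError("require A_master > A_mutant >= 0")
    space = list(space)
    try:
        m_idx = space.index(master)
    except ValueError:
        raise KeyError(f"master karyotype {master.copies} not in state space") from None
    A = np.full(len(space), float(A_mutant))
    A[m_idx] = float(A_master)
    if lethal_on_nullisomy:
        for i, k in enumerate(space):
            if min(k.copies) == 0:
                A[i] = 0.0
    D = np.full(len(space), float(D_uniform))
    return FitnessAssignment(A=A, D=D)


def mean_excess_production(x: PopulationState, f: FitnessAssignment) -> float:
    """Population mean excess production Ē = Σ_k (A_k − D_k) x_k."""
    if x.x.size != f.n_states:
        raise ValueError(
            f"population has {x.x.size} states, fitness has {f.n_states}"
        )
    return float(f.E_excess @ x.x)


def superiority(x: PopulationState, f: FitnessAssignment, m: int) -> float:
    """Superiority σ̄_m = A_m / (D_m + Ē_{k≠m}) of state m against competitors.

    Ē_{k≠m} is the competitor-frequency-normalized mean excess production.
    Raises if no competitors are present or the denominator is not positive.
    """
    if x.x.size != f.n_states:
        raise ValueError("population and fitness state spaces differ")
    if not (0 <= m < f.n_states):
        raise IndexError(f"state index {m} out of range")
    mask = np.ones(f.n_states, dtype=bool)
    mask[m] = False
    comp_freq = float(x.x[mask].sum())
    if comp_freq <= 0.0:
        raise ValueError("superiority undefined: no competitor frequency present")
    e_comp = float(f.E_excess[mask] @ x.x[mask]) / comp_freq
    denom = float(f.D[m]) + e_comp
    if denom <= 0.0:
        raise ValueError(f"superiority denominator must be positive, got {denom:.6g}")
    return float(f.A[m]) / denom
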