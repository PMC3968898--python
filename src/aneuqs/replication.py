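"""Per-copy aneuploid error model and karyotype transition kernel.

Replication fidelity is parameterized per physically distinct chromosome
copy: each copy is reproduced exactly once with probability 1 − E (the
aneuploid fidelity Ā = 1 − E), and with probability E it missegregates,
leaving either two copies in the daughter (gain, probability E·g) or none
(loss, probability E·(1−g)), independently across copies.  The probability
that a whole karyotype of length c is reproduced without any error is then

    Q_mm = Ā^c = (1 − E)^c,

the reproduction fidelity of the chromosomal master sequence.  E is the
aneuploidy rate: the average probability of at least one new copy-number
defect per chromosome copy per division.  The average is taken per copy,
not per unit type — that convention is what makes Q_mm = Ā^c exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import Karyotype, sequence_length

__all__ = [
    "ReplicationKernel",
    "replication_fidelity",
    "copy_event_distribution",
    "offspring_count_pmf",
    "karyotype_transition_probability",
    "build_transition_matrix",
]


@dataclass(frozen=True)
class ReplicationKernel:
    """Per-copy error model.

    Parameters
    ----------
    per_copy_error
        E, probability in [0, 1] that a given chromosome copy is not
        reproduced exactly once.
    gain_bias
        g, fraction of errors that are gains (daughter inherits two copies);
        the remaining fraction 1 − g are losses.  Default 0.5 — symmetric
        missegregation, the minimal completion of an aggregate fidelity.
    """

    per_copy_error: float
    gain_bias: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.per_copy_error <= 1.0):
            raise ValueError(f"per_copy_error must be in [0,1]: {self.per_copy_error}")
        if not (0.0 <= self.gain_bias <= 1.0):
            raise ValueError(f"gain_bias must be in [0,1]: {self.gain_bias}")

    @property
    def aneuploid_fidelity(self) -> float:
        """Ā = 1 − E, probability a copy is reproduced exactly once."""
        return 1.0 - self.per_copy_error


def replication_fidelity(k: Karyotype, kernel: ReplicationKernel) -> float:
    """Q_mm = Ā^c: probability the karyotype is reproduced exactly."""
    return kernel.aneuploid_fidelity ** sequence_length(k)


def copy_event_distribution(kernel: ReplicationKernel) -> tuple[float, float, float]:
    """Per-copy outcome probabilities (inherit 1, inherit 2, inherit 0).

    Returns (1 − E, E·g, E·(1 − g)); sums to 1 exactly.
    """
    e, g = kernel.per_copy_error, kernel.gain_bias
    p_gain = e * g
    p_loss = e * (1.0 - g)
    return (1.0 - e, p_gain, p_loss)


def offspring_count_pmf(n_copies: int, kernel: ReplicationKernel) -> np.ndarray:
    """PMF of the daughter copy count for a unit with ``n_copies`` copies.

    Each parent copy contributes 0, 1 or 2 copies independently; the daughter
    count is their sum, supported on 0..2·n_copies.  Computed by polynomial
    convolution of the per-copy generating function.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be non-negative")
    p1, p2, p0 = copy_event_distribution(kernel)
    base = np.array([p0, p1, p2], dtype=float)  # index = copies contributed
    pmf = np.array([1.0])
    for _ in range(n_copies):
        pmf = np.convolve(pmf, base)
    return pmf


def karyotype_transition_probability(
    parent: Karyotype, child: Karyotype, kernel: ReplicationKernel
) -> float:
    """P(daughter = child | mother = parent) under the per-copy model.

    Units segregate independently, so the probability factorizes over units.
    Gains and losses within a unit can cancel, so the diagonal
    P(parent → parent) exceeds the no-error fidelity Ā^c in general; the
    no-error *path* alone has probability exactly Ā^c.
    """
    if parent.n_units != child.n_units:
        raise ValueError(
            f"unit-set mismatch: parent has {parent.n_units} units, "
            f"child has {child.n_units}"
        )
    prob = 1.0
    for n, m in zip(parent.copies, child.copies):
        if m > 2 * n:
            return 0.0
        prob *= offspring_count_pmf(n, kernel)[m]
        if prob == 0.0:
            return 0.0
    return prob


def build_transition_matrix(
    space: Sequence[Karyotype], kernel: ReplicationKernel
) -> tuple[np.ndarray, np.ndarray]:
    """Dense transition matrix Q[child, parent] over an enumerated space.

    Returns ``(Q, escape)`` where ``escape[parent]`` is the probability mass
    of daughters falling outside the truncated space (copy counts past the
    enumeration bound).  Columns sum to 1 − escape: the operator is kept
    honestly sub-stochastic rather than renormalized, so truncation never
    inflates fidelity.  Downstream, escaped mass is treated as lethal.
    """
    space = list(space)
    n_states = len(space)
    if n_states == 0:
        raise ValueError("empty state space")
    n_units = space[0].n_units
    copies = np.array([k.copies for k in space], dtype=np.int64)  # (S, U)

    # per-unit pmf cache keyed by parent copy count
    max_n = int(copies.max(initial=0))
    pmfs = [offspring_count_pmf(n, kernel) for n in range(max_n + 1)]
    # pad to a rectangular lookup table: P[n, m] = P(daughter m | parent n)
    table = np.zeros((max_n + 1, 2 * max_n + 1))
    for n, pmf in enumerate(pmfs):
        table[n, : pmf.size] = pmf

    Q = np.ones((n_states, n_states))
    for u in range(n_units):
        # prob of each child count given each parent count, for this unit
        Q *= table[np.ix_(copies[:, u], copies[:, u])].T  # [child, parent]
    col_sums = Q.sum(axis=0)
    escape = np.clip(1.0 - col_sums, 0.0, None)
    return Q, escape
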