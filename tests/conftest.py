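import itertools

import pytest

from aneuqs.replication import ReplicationKernel, copy_event_distribution
from aneuqs.units import Karyotype, enumerate_karyotype_space


@pytest.fixture
def small_space():
    """All karyotypes over 2 units with copies in 0..3 (16 states)."""
    return enumerate_karyotype_space(2, 3)


@pytest.fixture
def kernel():
    return ReplicationKernel(per_copy_error=0.1, gain_bias=0.5)


def brute_force_transition(parent: Karyotype, child: Karyotype, kernel: ReplicationKernel) -> float:
    """Oracle: enumerate every per-copy outcome assignment jointly.

    Each chromosome copy contributes 0, 1 or 2 copies to the daughter; the
    daughter's count for a unit is the sum over that unit's parental copies.
    Enumerates all 3^(total copies) assignments — independent of the
    convolution implementation.
    """
    p1, p2, p0 = copy_event_distribution(kernel)
    outcome_prob = {0: p0, 1: p1, 2: p2}
    copy_units = [u for u, n in enumerate(parent.copies) for _ in range(n)]
    total = 0.0
    for assignment in itertools.product((0, 1, 2), repeat=len(copy_units)):
        counts = [0] * parent.n_units
        prob = 1.0
        for unit, contributed in zip(copy_units, assignment):
            counts[unit] += contributed
            prob *= outcome_prob[contributed]
        if tuple(counts) == child.copies:
            total += prob
    return total


@pytest.fixture
def oracle_transition():
    return brute_force_transition
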