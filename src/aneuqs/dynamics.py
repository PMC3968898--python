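"""Deterministic replicator–mutator (Eigen) dynamics and threshold scans.

The frequency x_m of karyotype m evolves as

    dx_m/dt = (W_mm − Ē(t)) x_m + Σ_{k≠m} W_mk x_k,

with value matrix W_mk = A_k Q_mk for k ≠ m (production of m by erroneous
reproduction of k) and W_mm = A_m Q_mm − D_m.  Ē(t) is the population mean
of the effective excess production Σ_k x_k (A_k s_k − D_k), where s_k is the
column sum of the transition kernel; with a full-support kernel s_k = 1 and
this is the textbook mean excess production Σ (A_k − D_k) x_k.  Mass that
escapes a truncated state space is thereby treated as lethal, and the flow
conserves the simplex exactly.

The flow is the projectivization of the linear system y' = W y
(x = y / Σ y), so trajectories are propagated with a precomputed matrix
exponential and per-step normalization, and the stationary state is the
normalized dominant (Perron) eigenvector of W.

The critical per-copy error rate at which the master's stationary frequency
collapses — the aneuploid error catastrophe — is located numerically by
``threshold_scan`` and compared against the analytic bound ln σ̄ / c.

Two transition models are available for the scan.  The exact convolution
kernel on an enumerated space is faithful to the per-copy event model but,
on low-dimensional spaces (few units), back-mutation into the master is
strong — a ±1 copy-number step is easily reversed — and the master mode
stays localized at every error rate, so no catastrophe occurs; this is a
real property of low-dimensional copy-number chains, not a numerical
artifact.  The error catastrophe belongs to the high-dimensional regime,
where an erroneous chromosome copy is subject to so many further possible
alterations that return to the master configuration is negligible.  That
regime is realized by the *error-class* model
(:func:`error_class_transition_matrix`): states are L1-distance classes
from the master, each of the c copies errs independently (new defects are
Binomial(c, E) per division), back-mutation is neglected, and the farthest
class lumps the remaining mutant cloud.  The master class then reproduces
itself with probability exactly (1 − E)^c and the scan exhibits the sharp
transition at σ̄ (1 − E)^c = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.stats

from .fitness import FitnessAssignment, PopulationState, superiority
from .replication import ReplicationKernel, build_transition_matrix
from .units import Karyotype, sequence_length

__all__ = [
    "DegenerateSpectrumError",
    "Trajectory",
    "ThresholdScanResult",
    "build_value_matrix",
    "integrate_replicator_mutator",
    "stationary_distribution",
    "threshold_scan",
    "error_class_transition_matrix",
    "error_class_threshold_scan",
]


class DegenerateSpectrumError(RuntimeError):
    """Dominant eigenvalue is complex or the Perron vector is not recoverable."""


def build_value_matrix(f: FitnessAssignment, Q: np.ndarray) -> np.ndarray:
    """Value matrix W from a fitness assignment and transition kernel.

    W[m, k] = A_k Q[m, k] for k ≠ m;  W[m, m] = A_m Q[m, m] − D_m.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"Q must be square, got shape {Q.shape}")
    if Q.shape[0] != f.n_states:
        raise ValueError(
            f"fitness has {f.n_states} states but Q is {Q.shape[0]}x{Q.shape[1]}"
        )
    W = Q * f.A[np.newaxis, :]
    W[np.diag_indices_from(W)] -= f.D
    return W


@dataclass(frozen=True)
class Trajectory:
    """Replicator–mutator trajectory: times, states (rows), final residual."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states), each row on the simplex
    residual: float  # ‖dx/dt‖₁ at the final point

    @property
    def final(self) -> PopulationState:
        return PopulationState(self.states[-1])


def _rhs(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    wx = W @ x
    return wx - wx.sum() * x


def integrate_replicator_mutator(
    W: np.ndarray,
    x0: PopulationState,
    t_end: float,
    dt: float = 0.5,
    n_records: int = 101,
) -> Trajectory:
    """Integrate the replicator–mutator flow from ``x0`` to ``t_end``.

    Uses the exact linear lift y' = W y: one matrix exponential
    P = exp(W·dt) is computed, then the state is propagated by repeated
    multiplication with per-step normalization (the normalization implements
    the −Ē(t)x term exactly).  Every recorded point lies on the simplex to
    machine precision; the residual of the right-hand side at the final
    point is reported so callers can judge stationarity.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    W = np.asarray(W, dtype=float)
    x = np.asarray(x0.x, dtype=float).copy()
    n_steps = max(1, math.ceil(t_end / dt))
    dt = t_end / n_steps
    P = scipy.linalg.expm(W * dt)

    record_at = np.unique(
        np.linspace(0, n_steps, num=min(n_records, n_steps + 1)).round().astype(int)
    )
    times = record_at * dt
    states = np.empty((record_at.size, x.size))
    rec = 0
    if record_at[0] == 0:
        states[0] = x
        rec = 1
    for step in range(1, n_steps + 1):
        x = P @ x
        total = x.sum()
        if not np.isfinite(total) or total <= 0:
            raise ArithmeticError(
                f"integration failed at step {step}: total mass {total!r} "
                "(all states dead or numerical overflow)"
            )
        x /= total
        if rec < record_at.size and step == record_at[rec]:
            states[rec] = x
            rec += 1
    residual = float(np.abs(_rhs(W, x)).sum())
    return Trajectory(times=times, states=states, residual=residual)


def stationary_distribution(W: np.ndarray, imag_tol: float = 1e-8) -> PopulationState:
    """Stationary quasispecies: normalized dominant eigenvector of W.

    The replicator–mutator flow converges to the Perron eigenvector of W
    (the steady state with dx/dt = 0).  A deterministic dense eigensolve is
    used.  Raises :class:`DegenerateSpectrumError` if the dominant
    eigenvalue is complex beyond tolerance or the eigenvector has mixed
    signs (reducible/degenerate spectrum).
    """
    W = np.asarray(W, dtype=float)
    vals, vecs = scipy.linalg.eig(W)
    idx = int(np.argmax(vals.real))
    lam = vals[idx]
    scale = max(1.0, float(np.abs(vals.real).max()))
    if abs(lam.imag) > imag_tol * scale:
        raise DegenerateSpectrumError(
            f"dominant eigenvalue {lam:.6g} has a non-negligible imaginary part"
        )
    v = vecs[:, idx]
    if np.abs(v.imag).max() > imag_tol * max(1.0, np.abs(v.real).max()):
        raise DegenerateSpectrumError("dominant eigenvector is complex")
    v = v.real
    if v.sum() < 0:
        v = -v
    if v.min() < -1e-8 * max(1.0, v.max()):
        raise DegenerateSpectrumError(
            "dominant eigenvector has mixed signs; W is reducible or degenerate "
            "on the requested support"
        )
    v = np.clip(v, 0.0, None)
    return PopulationState(v / v.sum())


@dataclass(frozen=True)
class ThresholdScanResult:
    """Numeric error-threshold scan over a per-copy error grid.

    ``detected_threshold`` is the first grid point where the stationary
    master frequency falls below the neutral expectation 1/(number of viable
    states); ``steepest_threshold`` is the grid midpoint of the steepest
    master-frequency drop.  ``analytic_threshold`` is ln σ̄ / c for
    comparison.  Either detection may be ``None`` if the scan shows no
    collapse on the grid.
    """

    error_grid: np.ndarray
    master_freq: np.ndarray
    leading_eigenvalue: np.ndarray
    detected_threshold: float | None
    steepest_threshold: float | None
    analytic_threshold: float
    neutral_level: float
    sigma_bar: float
    master_length: int

    def __post_init__(self) -> None:
        e = np.asarray(self.error_grid, dtype=float)
        if e.ndim != 1 or (np.diff(e) <= 0).any():
            raise ValueError("error_grid must be strictly increasing")


def _uniform_competitor_superiority(f: FitnessAssignment, m_idx: int) -> float:
    """σ̄ with competitors weighted uniformly over viable states.

    Used where the stationary population puts no mass on competitors (e.g. at
    E = 0).  For a single-peak landscape with uniform death rate this equals
    A_master / (D + (A_mutant − D)) = A_master / A_mutant when D = 0.
    """
    viable = f.A > 0
    viable[m_idx] = False
    if not viable.any():
        raise ValueError("no viable competitor states")
    x = np.zeros(f.n_states)
    x[viable] = 1.0 / viable.sum()
    # tiny mass on master is irrelevant: superiority ignores the master entry
    x[m_idx] = 0.0
    return superiority(PopulationState(x), f, m_idx)


def threshold_scan(
    space: Sequence[Karyotype],
    f: FitnessAssignment,
    master: Karyotype,
    error_grid: Sequence[float],
    gain_bias: float = 0.5,
    sigma_bar: float | None = None,
) -> ThresholdScanResult:
    """Scan stationary master frequency over a per-copy error grid.

    For each error rate on the grid the transition kernel, value matrix and
    stationary distribution are rebuilt and the master's stationary
    frequency recorded.  ``sigma_bar`` defaults to the uniform-competitor
    superiority of the landscape (see module docs).
    """
    space = list(space)
    m_idx = space.index(master)
    grid = np.asarray(error_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("error_grid must contain at least two points")
    if (np.diff(grid) <= 0).any():
        raise ValueError("error_grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] >= 1:
        raise ValueError("error_grid must lie in [0, 1)")

    if sigma_bar is None:
        sigma_bar = _uniform_competitor_superiority(f, m_idx)
    c_m = sequence_length(master)

    def build_W(e: float) -> np.ndarray:
        kernel = ReplicationKernel(per_copy_error=e, gain_bias=gain_bias)
        Q, _ = build_transition_matrix(space, kernel)
        return build_value_matrix(f, Q)

    n_viable = int((f.A > 0).sum())
    return _scan_grid(grid, build_W, m_idx, n_viable, float(sigma_bar), c_m)


def _scan_grid(
    grid: np.ndarray,
    build_W,
    m_idx: int,
    n_viable: int,
    sigma_bar: float,
    c_m: int,
) -> ThresholdScanResult:
    neutral = 1.0 / n_viable
    analytic = math.log(sigma_bar) / c_m if sigma_bar >= 1 else 0.0
    freqs = np.empty(grid.size)
    lead = np.empty(grid.size)
    for i, e in enumerate(grid):
        W = build_W(float(e))
        vals = scipy.linalg.eigvals(W)
        lead[i] = float(vals.real.max())
        freqs[i] = float(stationary_distribution(W).x[m_idx])

    below = np.nonzero(freqs < neutral)[0]
    detected = float(grid[below[0]]) if below.size else None
    slopes = np.diff(freqs) / np.diff(grid)
    steepest = None
    if (slopes < 0).any():
        j = int(np.argmin(slopes))
        steepest = float(0.5 * (grid[j] + grid[j + 1]))
    return ThresholdScanResult(
        error_grid=grid,
        master_freq=freqs,
        leading_eigenvalue=lead,
        detected_threshold=detected,
        steepest_threshold=steepest,
        analytic_threshold=analytic,
        neutral_level=neutral,
        sigma_bar=float(sigma_bar),
        master_length=c_m,
    )


def error_class_transition_matrix(
    c_m: int, per_copy_error: float, n_classes: int
) -> np.ndarray:
    """Transition matrix over L1-distance error classes from the master.

    Class 0 is the master karyotype; class j collects karyotypes at L1
    distance j, and the last class lumps everything at distance ≥ n_classes
    − 1.  Each of the c_m chromosome copies errs independently per division,
    so the number of new defects is Binomial(c_m, E) and a class-j parent
    moves to class j + k with that probability; back-mutation (an error that
    happens to cancel a previous defect) is neglected — in a many-unit
    karyotype space the fraction of error paths returning to the master
    configuration is vanishing.  Columns sum to 1; the lumped far class
    retains itself, playing the role of the aggregated mutant cloud.
    """
    if c_m < 1 or n_classes < 2:
        raise ValueError("need c_m >= 1 and n_classes >= 2")
    if not (0.0 <= per_copy_error < 1.0):
        raise ValueError("per_copy_error must be in [0, 1)")
    pmf = scipy.stats.binom.pmf(np.arange(n_classes), c_m, per_copy_error)
    Q = np.zeros((n_classes, n_classes))
    for j in range(n_classes - 1):
        span = n_classes - 1 - j
        Q[j : n_classes - 1, j] = pmf[:span]
        Q[n_classes - 1, j] = max(0.0, 1.0 - pmf[:span].sum())
    Q[n_classes - 1, n_classes - 1] = 1.0
    return Q


def error_class_threshold_scan(
    c_m: int,
    error_grid: Sequence[float],
    A_master: float,
    A_mutant: float = 1.0,
    D_uniform: float = 0.0,
    n_classes: int = 40,
    sigma_bar: float | None = None,
) -> ThresholdScanResult:
    """Threshold scan in the error-class (high-dimensional) regime.

    The tractable route for master-sequence lengths where full karyotype
    enumeration is infeasible.  The master class reproduces itself with
    probability exactly (1 − E)^c_m, so the scan exhibits the sharp
    error catastrophe at σ̄ (1 − E)^c_m = 1 that the analytic bound
    ln σ̄ / c_m linearizes.
    """
    grid = np.asarray(error_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or (np.diff(grid) <= 0).any():
        raise ValueError("error_grid must be strictly increasing with >= 2 points")
    A = np.full(n_classes, float(A_mutant))
    A[0] = float(A_master)
    f = FitnessAssignment(A=A, D=np.full(n_classes, float(D_uniform)))
    if sigma_bar is None:
        sigma_bar = _uniform_competitor_superiority(f, 0)

    def build_W(e: float) -> np.ndarray:
        Q = error_class_transition_matrix(c_m, e, n_classes)
        return build_value_matrix(f, Q)

    n_viable = int((f.A > 0).sum())
    return _scan_grid(grid, build_W, 0, n_viable, float(sigma_bar), c_m)
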