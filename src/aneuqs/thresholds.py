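"""Closed-form viability and error-threshold formulas.

A master sequence of length L survives mutation–selection balance only if
its superiority outweighs its copying losses, σ̄ Q > 1 with Q = q̄^L.  Taking
logs and linearizing ln q̄ ≈ −(1 − q̄) gives the error-threshold inequality

    ln σ̄ / L  ≥  1 − q̄,

so the critical per-symbol error rate is T = ln σ̄ / L.  The same formula
serves two regimes that differ only in what a "symbol" is:

* nucleotide regime — L = v, the master sequence length in nucleotides, and
  1 − q̄ the per-nucleotide error rate;
* aneuploid regime — L = c, the total chromosome copy number, and
  1 − Ā = E the per-copy aneuploidy rate.

In the aneuploid regime with σ̄ ∈ [10², 10³] and c ≈ 10² the threshold is of
order 10⁻², inside the measured range of cancer aneuploidy rates
[10⁻³, 10⁻¹] — aneuploid tumor populations operate close to their error
catastrophe.  In the nucleotide regime the same algebra fails for
mismatch-repair-deficient (MSI) tumors: their elevated point-mutation rates
exceed the bound by orders of magnitude, yet such tumors exist — the
inconsistency quantified by :func:`msi_viability_report`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ThresholdReport",
    "HumanRegimeDefaults",
    "HUMAN_DEFAULTS",
    "viability",
    "error_threshold",
    "exact_error_threshold",
    "nucleotide_threshold",
    "aneuploid_threshold",
    "msi_viability_report",
]


@dataclass(frozen=True)
class HumanRegimeDefaults:
    """Canonical human-cell parameter set for both regimes.

    genome_length: nucleotides in the human genome (~3.2e9).
    coding_fraction: conserved/coding share of the genome (~5%).
    baseline_error_rates: healthy per-nucleotide error rates per division.
    msi_multipliers: fold-elevation of nucleotide error under mismatch-repair
        loss (1 to 3 orders of magnitude).
    sigma_values: plausible superiority range for dominant subpopulations.
    c_m: typical chromosomal master-sequence length of a highly aneuploid
        tumor cell (order 1e2).
    cancer_aneuploidy_range: measured per-copy aneuploidy rates in cancer.
    """

    genome_length: float = 3.2e9
    coding_fraction: float = 0.05
    baseline_error_rates: tuple[float, ...] = (1e-10, 1e-9)
    msi_multipliers: tuple[float, ...] = (1e1, 1e2, 1e3)
    sigma_values: tuple[float, ...] = (1e2, 1e3)
    c_m: float = 1e2
    cancer_aneuploidy_range: tuple[float, float] = (1e-3, 1e-1)

    @property
    def coding_length(self) -> float:
        return self.genome_length * self.coding_fraction


HUMAN_DEFAULTS = HumanRegimeDefaults()


@dataclass(frozen=True)
class ThresholdReport:
    """One viability verdict: regime, inputs, bound, and the comparison."""

    regime: str  # "nucleotide" | "aneuploid"
    sigma_bar: float
    length: float
    bound: float  # ln σ̄ / length (or the exact form, if requested)
    error_rate: float
    viable: bool


def viability(sigma_bar: float, Q: float) -> bool:
    """Survival condition σ̄ Q > 1 (strict)."""
    if sigma_bar <= 0:
        raise ValueError("sigma_bar must be positive")
    if not (0.0 <= Q <= 1.0):
        raise ValueError("Q must be a probability")
    return sigma_bar * Q > 1.0


def error_threshold(sigma_bar: float, length: float) -> float:
    """Critical per-symbol error rate T = ln σ̄ / length (linearized form)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if sigma_bar <= 0:
        raise ValueError("sigma_bar must be positive")
    if sigma_bar < 1:
        warnings.warn(
            "sigma_bar < 1: the threshold bound is negative — the master "
            "sequence is not maintainable at any error rate",
            stacklevel=2,
        )
    return math.log(sigma_bar) / length


def exact_error_threshold(sigma_bar: float, length: float) -> float:
    """Exact critical error rate 1 − σ̄^(−1/length), i.e. 1 − exp(−ln σ̄/L).

    Solves σ̄ (1 − E)^L = 1 for E without linearizing; differs from
    :func:`error_threshold` near the threshold (the linearized form is
    slightly larger).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if sigma_bar <= 0:
        raise ValueError("sigma_bar must be positive")
    return 1.0 - sigma_bar ** (-1.0 / length)


def nucleotide_threshold(sigma_bar: float, v: float) -> float:
    """Per-nucleotide error threshold ln σ̄ / v for a sequence of v bases."""
    return error_threshold(sigma_bar, v)


def aneuploid_threshold(sigma_bar: float, c: float) -> float:
    """Per-copy aneuploid error threshold T(E) = ln σ̄ / c."""
    return error_threshold(sigma_bar, c)


def msi_viability_report(
    baseline_error_range: Sequence[float] = HUMAN_DEFAULTS.baseline_error_rates,
    msi_multipliers: Sequence[float] = HUMAN_DEFAULTS.msi_multipliers,
    sigma_range: Sequence[float] = HUMAN_DEFAULTS.sigma_values,
    v_options: Sequence[float] = (
        HUMAN_DEFAULTS.genome_length,
        HUMAN_DEFAULTS.coding_length,
    ),
    exact: bool = False,
) -> pd.DataFrame:
    """Nucleotide-regime viability grid for mismatch-repair-deficient cells.

    For every combination of baseline error rate, MSI fold-elevation,
    superiority and master-sequence length, compares the elevated error rate
    against the nucleotide error threshold and records the verdict.  The
    frame's ``attrs["any_viable"]`` flags whether any combination survives;
    in the human parameter regime essentially none do, which is the
    inconsistency that motivates moving the theory to the aneuploid regime.
    """
    if not (len(baseline_error_range) and len(msi_multipliers)
            and len(sigma_range) and len(v_options)):
        raise ValueError("all parameter ranges must be non-empty")
    bound_fn = exact_error_threshold if exact else error_threshold
    rows = []
    for base, mult, sigma, v in itertools.product(
        baseline_error_range, msi_multipliers, sigma_range, v_options
    ):
        err = base * mult
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bound = bound_fn(sigma, v)
        rows.append(
            {
                "baseline_error": base,
                "msi_multiplier": mult,
                "error_rate": err,
                "sigma_bar": sigma,
                "v": v,
                "bound": bound,
                "viable": bound >= err,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["any_viable"] = bool(df["viable"].any())
    return df
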