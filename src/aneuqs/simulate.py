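"""Finite-population karyotype evolution and the two-site synthetic dataset.

A Wright–Fisher model with non-overlapping generations: each generation, N
offspring choose parents by fitness-weighted multinomial sampling, and every
offspring karyotype is drawn from the per-copy replication kernel applied to
its parent.  Copy numbers past a configurable cap, and nullisomies, are
lethal (fitness 0) rather than clipped, so the kernel is never silently
distorted.

``generate_two_site_dataset`` emulates the single-cell copy-number design
behind the adaptive-aneuploidy argument: a primary tumor population grows
from a founder clone at one aneuploidy rate; a single aneuploid cell sampled
from it seeds a metastatic population that evolves at another (typically
higher) rate; both sites are then sampled as integer copy-number matrices.
The default scenario uses a 23-unit diploid founder (c = 46), N = 300, 16
generations per site, 100 sampled cells, and per-copy error rates 0.02
(primary) vs 0.10 (metastatic) — a five-fold elevation, with both rates
inside the measured cancer range [1e-3, 1e-1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .replication import ReplicationKernel
from .units import Karyotype, diploid

__all__ = [
    "ExtinctionError",
    "CellPopulationSample",
    "TwoSiteDataset",
    "TWO_SITE_DEFAULTS",
    "viability_fitness",
    "reproduce_copies",
    "wright_fisher_generation",
    "simulate_population",
    "generate_two_site_dataset",
]


class ExtinctionError(RuntimeError):
    """Every cell in the population has zero fitness."""


#: Default two-site scenario parameters (see module docstring).
TWO_SITE_DEFAULTS: dict = {
    "n_units": 23,
    "N": 300,
    "n_cells": 100,
    "E_primary": 0.02,
    "E_metastatic": 0.10,
    "generations_primary": 16,
    "generations_metastatic": 16,
    "gain_bias": 0.5,
    "max_copy": 8,
}


@dataclass
class CellPopulationSample:
    """A sampled cell population: one integer copy-number row per cell."""

    copies: np.ndarray  # (n_cells, n_units) int64
    generation: int
    site_label: str
    rng_seed: int
    unit_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if self.copies.ndim != 2 or self.copies.shape[0] == 0:
            raise ValueError("population must be a non-empty (cells x units) matrix")
        if (self.copies < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.copies.shape[0]

    @property
    def karyotypes(self) -> list[Karyotype]:
        return [Karyotype(tuple(row)) for row in self.copies]


def viability_fitness(
    max_copy: int = 8, lethal_on_nullisomy: bool = True
) -> Callable[[np.ndarray], np.ndarray]:
    """Flat fitness over viable karyotypes; cap breaches and nullisomy lethal."""

    def fitness(copies: np.ndarray) -> np.ndarray:
        ok = (copies <= max_copy).all(axis=1)
        if lethal_on_nullisomy:
            ok &= (copies >= 1).all(axis=1)
        return ok.astype(float)

    return fitness


def reproduce_copies(
    copies: np.ndarray, kernel: ReplicationKernel, rng: np.random.Generator
) -> np.ndarray:
    """Daughter copy-number matrix: per-copy i.i.d. gain/loss events.

    For a unit with n copies, k ~ Binomial(n, E) copies missegregate and
    g ~ Binomial(k, gain_bias) of those are gains, leaving n − k + 2g copies.
    """
    n = np.asarray(copies, dtype=np.int64)
    errs = rng.binomial(n, kernel.per_copy_error)
    gains = rng.binomial(errs, kernel.gain_bias)
    return n - errs + 2 * gains


def wright_fisher_generation(
    pop: CellPopulationSample,
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    kernel: ReplicationKernel,
    N: int,
    rng: np.random.Generator,
) -> CellPopulationSample:
    """One Wright–Fisher generation: select N parents, replicate each once."""
    if N < 1:
        raise ValueError("N must be >= 1")
    w = np.asarray(fitness_fn(pop.copies), dtype=float)
    if (w < 0).any():
        raise ValueError("fitness must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ExtinctionError(
            f"population extinct at generation {pop.generation}: all fitness zero"
        )
    parents = rng.choice(pop.n_cells, size=N, p=w / total)
    children = reproduce_copies(pop.copies[parents], kernel, rng)
    return CellPopulationSample(
        copies=children,
        generation=pop.generation + 1,
        site_label=pop.site_label,
        rng_seed=pop.rng_seed,
        unit_ids=pop.unit_ids,
    )


def simulate_population(
    founder: Karyotype,
    kernel: ReplicationKernel,
    N: int,
    generations: int,
    seed: int | np.random.SeedSequence,
    fitness_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    site_label: str = "population",
    unit_lengths: Sequence[float] | None = None,
) -> tuple[CellPopulationSample, pd.DataFrame]:
    """Evolve N copies of a founder clone for a number of generations.

    Returns the final-generation population and a per-generation summary
    (mean L1 distance to the founder and mean total DNA content).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if fitness_fn is None:
        fitness_fn = viability_fitness()
    root = founder.as_array()
    lengths = (
        np.ones(founder.n_units)
        if unit_lengths is None
        else np.asarray(unit_lengths, dtype=float)
    )
    seed_repr = int(ss.entropy % (2**63)) if ss.entropy is not None else 0
    pop = CellPopulationSample(
        copies=np.tile(root, (N, 1)),
        generation=0,
        site_label=site_label,
        rng_seed=seed_repr,
    )
    records = [_summary_row(pop, root, lengths)]
    for _ in range(generations):
        pop = wright_fisher_generation(pop, fitness_fn, kernel, N, rng)
        records.append(_summary_row(pop, root, lengths))
    return pop, pd.DataFrame.from_records(records)


def _summary_row(pop: CellPopulationSample, root: np.ndarray, lengths: np.ndarray) -> dict:
    return {
        "generation": pop.generation,
        "mean_l1_to_founder": float(np.abs(pop.copies - root).sum(axis=1).mean()),
        "mean_dna_content": float((pop.copies @ lengths).mean()),
    }


@dataclass
class TwoSiteDataset:
    """Paired primary/metastatic copy-number matrices plus ground truth."""

    primary: np.ndarray  # (n_cells, n_units) int64
    metastasis: np.ndarray
    unit_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)


def generate_two_site_dataset(
    founder: Karyotype | None = None,
    E_primary: float = TWO_SITE_DEFAULTS["E_primary"],
    E_metastatic: float = TWO_SITE_DEFAULTS["E_metastatic"],
    generations_primary: int = TWO_SITE_DEFAULTS["generations_primary"],
    generations_metastatic: int = TWO_SITE_DEFAULTS["generations_metastatic"],
    N: int = TWO_SITE_DEFAULTS["N"],
    n_cells: int = TWO_SITE_DEFAULTS["n_cells"],
    seed: int = 0,
    gain_bias: float = TWO_SITE_DEFAULTS["gain_bias"],
    max_copy: int = TWO_SITE_DEFAULTS["max_copy"],
) -> TwoSiteDataset:
    """Synthesize paired primary/metastatic single-cell copy-number samples.

    The primary population evolves from the founder at ``E_primary``; one
    aneuploid cell (differing from the founder, if any exists) sampled from
    the primary's final generation seeds the metastatic population, which
    evolves at ``E_metastatic``.  ``n_cells`` cells are sampled without
    replacement from each site.  The returned metadata records both true
    rates, the seed, and the metastasis-seeding cell, for recovery tests.
    Identical seed and parameters give byte-identical matrices.
    """
    if founder is None:
        founder = diploid(TWO_SITE_DEFAULTS["n_units"])
    for name, e in (("E_primary", E_primary), ("E_metastatic", E_metastatic)):
        if not (0.0 <= e < 1.0):
            raise ValueError(f"{name} must be in [0, 1): {e}")
    if n_cells > N:
        raise ValueError(f"n_cells ({n_cells}) cannot exceed N ({N})")

    ss = np.random.SeedSequence(seed)
    ss_primary, ss_pick, ss_met, ss_sample = ss.spawn(4)
    fitness_fn = viability_fitness(max_copy=max_copy)

    kern_p = ReplicationKernel(per_copy_error=E_primary, gain_bias=gain_bias)
    primary_pop, _ = simulate_population(
        founder, kern_p, N, generations_primary, ss_primary,
        fitness_fn=fitness_fn, site_label="primary",
    )

    # seed the metastasis from the aneuploid subpopulation of the primary;
    # the seeding cell proliferates, so it must itself be viable
    rng_pick = np.random.default_rng(ss_pick)
    root = founder.as_array()
    dist = np.abs(primary_pop.copies - root).sum(axis=1)
    viable = fitness_fn(primary_pop.copies) > 0
    candidates = np.nonzero((dist > 0) & viable)[0]
    if candidates.size == 0:
        candidates = np.nonzero(viable)[0]
    if candidates.size == 0:
        raise ExtinctionError("no viable cell in the primary to seed the metastasis")
    seed_cell = primary_pop.copies[rng_pick.choice(candidates)]

    kern_m = ReplicationKernel(per_copy_error=E_metastatic, gain_bias=gain_bias)
    met_pop, _ = simulate_population(
        Karyotype(tuple(seed_cell)), kern_m, N, generations_metastatic, ss_met,
        fitness_fn=fitness_fn, site_label="metastasis",
    )

    rng_sample = np.random.default_rng(ss_sample)
    idx_p = np.sort(rng_sample.choice(N, size=n_cells, replace=False))
    idx_m = np.sort(rng_sample.choice(N, size=n_cells, replace=False))
    unit_ids = tuple(f"unit{i + 1}" for i in range(founder.n_units))
    metadata = {
        "E_primary": E_primary,
        "E_metastatic": E_metastatic,
        "gain_bias": gain_bias,
        "generations_primary": generations_primary,
        "generations_metastatic": generations_metastatic,
        "N": N,
        "n_cells": n_cells,
        "max_copy": max_copy,
        "seed": seed,
        "founder": [int(c) for c in founder.copies],
        "metastasis_seed_cell": [int(c) for c in seed_cell],
        "unit_ids": list(unit_ids),
    }
    return TwoSiteDataset(
        primary=primary_pop.copies[idx_p],
        metastasis=met_pop.copies[idx_m],
        unit_ids=unit_ids,
        metadata=metadata,
    )
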