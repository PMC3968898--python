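"""Population statistics for single-cell copy-number samples.

Implements the phenomenological toolkit behind the adaptive-aneuploidy
argument: per-cell Euclidean distances to a common root profile, a
Levene/Brown–Forsythe test for equality of distance variances between two
sites, a right-tail weight statistic for ploidy (total DNA content)
distributions, and a per-copy aneuploidy-rate estimator from parent–child
karyotype pairs.  A higher aneuploidy rate in one site shows up as a larger
variance of root distances and a heavier supra-modal ploidy tail; the
variance test is the headline comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats
from scipy.spatial.distance import pdist
from statsmodels.stats.proportion import proportion_confint

from .units import Karyotype

__all__ = [
    "DistanceSet",
    "VarianceTestResult",
    "AneuploidyRateEstimate",
    "distance_to_root",
    "median_root_profile",
    "pairwise_distances",
    "brown_forsythe_statistic",
    "levene_variance_test",
    "ploidy_tail_weight",
    "estimate_aneuploidy_rate",
]


@dataclass(frozen=True)
class DistanceSet:
    """Per-cell Euclidean distances to a common root profile."""

    distances: np.ndarray
    group_label: str
    root_profile: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "root_profile", np.asarray(self.root_profile))


def distance_to_root(
    profiles: np.ndarray, root: Sequence[int] | np.ndarray, group_label: str = ""
) -> DistanceSet:
    """Euclidean (L2) distance of every copy-number profile to the root."""
    profiles = np.asarray(profiles, dtype=float)
    root_arr = np.asarray(root, dtype=float)
    if profiles.ndim != 2 or root_arr.ndim != 1 or profiles.shape[1] != root_arr.size:
        raise ValueError(
            f"profiles {profiles.shape} and root {root_arr.shape} do not share a unit set"
        )
    d = np.sqrt(((profiles - root_arr) ** 2).sum(axis=1))
    return DistanceSet(distances=d, group_label=group_label, root_profile=root_arr)


def median_root_profile(profiles: np.ndarray) -> np.ndarray:
    """Integer-rounded per-unit median profile of a pooled sample.

    The fallback common root when the founder karyotype is unknown.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise ValueError("profiles must be a non-empty (cells x units) matrix")
    return np.rint(np.median(profiles, axis=0)).astype(np.int64)


def pairwise_distances(profiles: np.ndarray) -> np.ndarray:
    """Condensed vector of mutual Euclidean distances between profiles."""
    return pdist(np.asarray(profiles, dtype=float))


@dataclass(frozen=True)
class VarianceTestResult:
    statistic: float
    p_value: float
    method: str  # "f" | "permutation"
    center: str  # "median" | "mean"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def _center(values: np.ndarray, center: str, axis: int = -1) -> np.ndarray:
    if center == "median":
        return np.median(values, axis=axis, keepdims=True)
    if center == "mean":
        return np.mean(values, axis=axis, keepdims=True)
    raise ValueError(f"center must be 'median' or 'mean', got {center!r}")


def brown_forsythe_statistic(
    group1: np.ndarray, group2: np.ndarray, center: str = "median"
) -> float:
    """Levene-type F statistic on absolute deviations from the group centers.

    With ``center='median'`` this is the Brown–Forsythe variant.  The
    statistic is the one-way ANOVA F computed on z_ij = |y_ij − center_i|.
    """
    z1 = np.abs(group1 - _center(group1, center))
    z2 = np.abs(group2 - _center(group2, center))
    return _anova_f(z1[None, :], z2[None, :])[0]


def _anova_f(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Vectorized two-group one-way F on rows of z1/z2 (shape (B, n_i))."""
    n1, n2 = z1.shape[1], z2.shape[1]
    ntot = n1 + n2
    m1 = z1.mean(axis=1)
    m2 = z2.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / ntot
    between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    within = ((z1 - m1[:, None]) ** 2).sum(axis=1) + ((z2 - m2[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ntot - 2) * between / within
    f = np.where((between == 0) & (within == 0), 0.0, f)
    return np.where(np.isfinite(f), f, np.inf)


def levene_variance_test(
    group1: Sequence[float],
    group2: Sequence[float],
    center: str = "median",
    method: str = "f",
    n_perm: int = 9999,
    seed: int | None = None,
) -> VarianceTestResult:
    """Test equality of variances between two groups.

    The default is the Brown–Forsythe variant (absolute deviations from the
    group medians, one-way F), which is robust to the skewed distance
    distributions karyotype evolution produces.  ``method='f'`` uses the
    F-distribution approximation; ``method='permutation'`` shuffles group
    labels ``n_perm`` times and reports p = (1 + #{F_perm ≥ F_obs}) /
    (1 + n_perm).  If every absolute deviation is zero in both groups, the
    result is statistic 0, p 1, with a warning.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group must contain at least 3 observations")
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1[0] == g2[0]:
        raise ValueError("all values identical across both groups")

    z1 = np.abs(g1 - _center(g1, center))
    z2 = np.abs(g2 - _center(g2, center))
    if (z1 == 0).all() and (z2 == 0).all():
        warnings.warn("all absolute deviations are zero; variance test degenerate")
        return VarianceTestResult(0.0, 1.0, method=method, center=center)

    if method == "f":
        scipy_center = {"median": "median", "mean": "mean"}[center]
        stat, p = scipy.stats.levene(g1, g2, center=scipy_center)
        return VarianceTestResult(float(stat), float(p), method="f", center=center)
    if method == "permutation":
        obs = brown_forsythe_statistic(g1, g2, center=center)
        pooled = np.concatenate([g1, g2])
        rng = np.random.default_rng(seed)
        n1 = g1.size
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[order]
        p1 = np.abs(perm[:, :n1] - _center(perm[:, :n1], center))
        p2 = np.abs(perm[:, n1:] - _center(perm[:, n1:], center))
        f_perm = _anova_f(p1, p2)
        p = (1.0 + (f_perm >= obs).sum()) / (1.0 + n_perm)
        return VarianceTestResult(float(obs), float(p), method="permutation", center=center)
    raise ValueError(f"method must be 'f' or 'permutation', got {method!r}")


def ploidy_tail_weight(
    dna_contents: Sequence[float], delta: float, side: str = "right"
) -> float:
    """Fraction of cells beyond (1 + delta) × the modal DNA content.

    The mode is located as the center of the highest-count histogram bin,
    with bin width by the Freedman–Diaconis rule (falling back to Sturges
    when the interquartile range vanishes).  A thicker right tail relative
    to the modal ploidy peak indicates greater aneuploid variability.
    """
    x = np.asarray(dna_contents, dtype=float)
    if x.size == 0:
        raise ValueError("dna_contents must be non-empty")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if side != "right":
        raise ValueError("only side='right' is implemented")
    edges = np.histogram_bin_edges(x, bins="fd")
    if edges.size < 3:  # degenerate FD width (zero IQR): fall back
        edges = np.histogram_bin_edges(x, bins="sturges")
    counts, edges = np.histogram(x, bins=edges)
    j = int(np.argmax(counts))
    mode = 0.5 * (edges[j] + edges[j + 1])
    return float((x > (1.0 + delta) * mode).mean())


@dataclass(frozen=True)
class AneuploidyRateEstimate:
    """Per-copy aneuploidy-rate estimate with a Wilson 95% interval.

    The estimate Ê = Σ L1(parent, child) / Σ c_parent counts net copy-number
    changes per parental chromosome copy.  Offsetting gains and losses
    within one unit cancel in the L1 distance, so Ê is a (slight) lower
    bound on the true per-copy error rate.
    """

    estimate: float
    ci_low: float
    ci_high: float
    n_changes: int
    n_copies: int


def estimate_aneuploidy_rate(
    parent_child_pairs: Iterable[tuple], confidence: float = 0.95
) -> AneuploidyRateEstimate:
    """Estimate the per-copy aneuploidy rate from parent–child karyotype pairs."""
    changes = 0
    copies = 0
    n_pairs = 0
    for parent, child in parent_child_pairs:
        p = parent.as_array() if isinstance(parent, Karyotype) else np.asarray(parent, dtype=np.int64)
        c = child.as_array() if isinstance(child, Karyotype) else np.asarray(child, dtype=np.int64)
        if p.shape != c.shape:
            raise ValueError("parent and child must share a unit set")
        changes += int(np.abs(p - c).sum())
        copies += int(p.sum())
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("need at least one parent-child pair")
    if copies == 0:
        raise ValueError("total parental copy number is zero")
    lo, hi = proportion_confint(min(changes, copies), copies,
                                alpha=1.0 - confidence, method="wilson")
    return AneuploidyRateEstimate(
        estimate=changes / copies,
        ci_low=float(lo),
        ci_high=float(hi),
        n_changes=changes,
        n_copies=copies,
    )
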