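"""Randomization-based significance for dyadic targets.

The sampling universe R is the zero-padded vector of all dyad-slot weights
of the completed graph (one entry per possible edge; multigraphs add one
entry per extra multi-edge).  For a subgroup whose target was normalized
over ``size`` slots, we draw r random slot subsets of that size without
replacement, record the per-draw statistic (mean or population variance),
and locate the subgroup's value by a z-score.  When the Shapiro–Wilk test
rejects normality of the r sampled statistics, the empirical (add-one)
p-value replaces the normal-law p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FAMILIES = {
    "qS": ("undirected", "simple"),
    "qM": ("undirected", "multi"),
    "qDS": ("directed", "simple"),
    "qDM": ("directed", "multi"),
    "qB": ("undirected", "simple"),
    "qBD": ("directed", "simple"),
    "qBM": (None, "multi"),  # directed in the reference setting; undirected reuse allowed
}


class DegenerateNullError(RuntimeError):
    """All sampled statistics are identical; no z-score can be formed."""


@dataclass
class SamplingUniverse:
    """Zero-padded slot weights of the completed graph."""

    weights: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("universe weights must be a vector")

    @property
    def N(self) -> int:
        return int(self.weights.size)


@dataclass
class NullDistribution:
    """r per-draw statistics with their summary."""

    sample_stats: np.ndarray
    seed: int
    statistic: str = "mean"

    def __post_init__(self) -> None:
        self.sample_stats = np.asarray(self.sample_stats, dtype=float)

    @property
    def r(self) -> int:
        return int(self.sample_stats.size)

    @property
    def mean(self) -> float:
        return float(self.sample_stats.mean())

    @property
    def sd(self) -> float:
        # a constant sample must be exactly degenerate (ptp == 0), not a
        # floating-point hair above zero
        if np.ptp(self.sample_stats) == 0:
            return 0.0
        return float(self.sample_stats.std(ddof=0))


def build_universe(graph, measure: str) -> SamplingUniverse:
    """Slot-weight vector for a measure family.

    Simple families have n(n-1)/2 (undirected) or n(n-1) (directed) slots;
    multi families add one slot per extra multi-edge of an observed dyad.
    Observed weights fill their slots; everything else is zero.
    """
    directedness, kind = FAMILIES[measure]
    if directedness is not None and (directedness == "directed") != graph.directed:
        raise ValueError(f"measure {measure} expects a "
                         f"{'directed' if directedness == 'directed' else 'undirected'} graph")
    if (kind == "multi") != graph.multi:
        raise ValueError(f"measure {measure} expects a {'multi' if kind == 'multi' else 'simple'} graph")
    n = len(graph.nodes)
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    base = n * (n - 1) if graph.directed else n * (n - 1) // 2
    observed = [w for _, _, _, w in graph.edges]
    if not graph.multi and len(observed) > base:
        raise ValueError("more observed edges than slots")
    n_zero = base - len(graph.weight_by_pair()) if graph.multi else base - len(observed)
    weights = np.concatenate([np.asarray(observed, dtype=float), np.zeros(n_zero)])
    return SamplingUniverse(weights, measure)


def _row_statistics(values: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "mean":
        return values.mean(axis=1)
    if statistic == "variance":
        return values.var(axis=1, ddof=0)
    raise ValueError(f"unknown statistic {statistic!r}")


def sample_null(universe: SamplingUniverse, size: int, r: int, seed: int,
                statistic: str = "mean") -> NullDistribution:
    """r draws of ``size`` slots without replacement (slots replaced between
    draws); deterministic under a fixed seed."""
    if not 1 <= size <= universe.N:
        raise ValueError(f"sample size {size} outside 1..{universe.N}")
    if r < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    w = universe.weights
    if size == universe.N:
        stat = _row_statistics(w[None, :], statistic)[0]
        return NullDistribution(np.full(r, stat), seed, statistic)
    # a uniform key per slot and draw; the size smallest keys form a uniform
    # random subset without replacement
    keys = rng.random((r, universe.N))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    stats_ = _row_statistics(w[idx], statistic)
    return NullDistribution(stats_, seed, statistic)


def z_score(t_p: float, null: NullDistribution) -> float:
    """(t_P - mean of sampled statistics) / their sd."""
    if null.sd == 0:
        raise DegenerateNullError("null distribution has zero spread")
    return (t_p - null.mean) / null.sd


def normality_check(null: NullDistribution, alpha: float = 0.05):
    """Shapiro–Wilk on the sampled statistics: (statistic, p, passed)."""
    if null.r < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    if np.ptp(null.sample_stats) == 0:
        return float("nan"), 0.0, False
    stat, p = stats.shapiro(null.sample_stats)
    return float(stat), float(p), bool(p >= alpha)


def empirical_p(t_p: float, null: NullDistribution, tail: str = "two_sided") -> float:
    """Add-one empirical p-value against the sampled statistics."""
    upper = (1 + int(np.sum(null.sample_stats >= t_p))) / (null.r + 1)
    lower = (1 + int(np.sum(null.sample_stats <= t_p))) / (null.r + 1)
    if tail == "upper":
        return upper
    if tail == "lower":
        return lower
    if tail == "two_sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown tail {tail!r}")


def normal_p(z: float, tail: str = "two_sided") -> float:
    """p-value from the normal law for a z-score."""
    if tail == "upper":
        return float(stats.norm.sf(z))
    if tail == "lower":
        return float(stats.norm.cdf(z))
    if tail == "two_sided":
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown tail {tail!r}")
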