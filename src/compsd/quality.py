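"""The seven dyadic quality functions.

All seven rank a pattern P by the z-score of its normalized dyadic target
t_P against the sampling null model.  They differ in the slot universe the
mean (or population variance) is taken over:

========  ==========  =====  ==============================================
measure   graph       dir.   denominator of t_P
========  ==========  =====  ==============================================
q_S       simple      no     n_E = n_EP (n_EP - 1)/2, covered node set
q_M       multi       no     n_E + m_E,  m_E = sum_i (m_i - 1)
q_DS      simple      yes    n_E = n_EP (n_EP - 1)
q_DM      multi       yes    n_E + m_E
q_B       simple      no     |E_CP|: completed-graph slots covered by P
q_BD      simple      yes    |E_SP|: same, directed
q_BM      multi       yes*   |E_MP|: same, plus observed multi-edges
========  ==========  =====  ==============================================

The subgraph-normalized family (q_S/q_M/q_DS/q_DM) sums the weights of the
covered observed edges and normalizes over *all* possible dyads among the
covered nodes; the balanced family (q_B/q_BD/q_BM) normalizes over only the
dyads whose labels are compatible with the pattern, in the completed graph.
(*) q_BM is presented for the directed case; the undirected multigraph
variant reuses the same slot semantics with unordered slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import nullmodel
from .core import AttributedDyadTable, Pattern, extension
from .nullmodel import (DegenerateNullError, NullDistribution, build_universe,
                        empirical_p, normal_p, normality_check, sample_null,
                        z_score)

SUBGRAPH_MEASURES = ("qS", "qM", "qDS", "qDM")
BALANCED_MEASURES = ("qB", "qBD", "qBM")
MEASURES = SUBGRAPH_MEASURES + BALANCED_MEASURES


@dataclass(frozen=True)
class QualitySpec:
    """Which measure to compute and how to calibrate its null."""

    measure: str = "qS"
    metric: str = "mean"          # "mean" | "variance"
    r: int = 1000                 # null samples
    seed: int = 0
    alpha: float = 0.05           # Shapiro-Wilk level for the normality gate
    tail: str = "two_sided"       # tail for the reported p-value
    a: float = 1.0                # exponent of the classical q_a baseline

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.metric not in ("mean", "variance"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0 <= self.a <= 1:
            raise ValueError("baseline exponent a must lie in [0, 1]")

    def check_compatible(self, directed: bool, multi: bool) -> None:
        want_dir, want_kind = nullmodel.FAMILIES[self.measure]
        if want_dir is not None and (want_dir == "directed") != directed:
            raise ValueError(
                f"{self.measure} requires a {'directed' if want_dir == 'directed' else 'undirected'} graph"
            )
        if (want_kind == "multi") != multi:
            raise ValueError(
                f"{self.measure} requires a {'multi' if want_kind == 'multi' else 'simple'} graph"
            )


@dataclass(frozen=True)
class TargetValue:
    """Normalized target of a pattern with its bookkeeping."""

    t_p: float
    denominator: int
    weight_sum: float
    covered_nodes: int
    covered_edges: int


@dataclass(frozen=True)
class SubgroupResult:
    """One row of a ranked result table."""

    pattern: Pattern
    n_nodes: int
    n_edges: int
    t_p: float
    z: float
    p: float
    denominator: int
    normality_passed: bool
    normality_p: float

    def as_row(self) -> dict:
        return {
            "pattern": self.pattern.render() or "<universal>",
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "t_P": self.t_p,
            "z": self.z,
            "p": self.p,
            "denominator": self.denominator,
        }


def possible_edges(n_nodes: int, directed: bool,
                   multiplicities=None) -> int:
    """Number of dyad slots over ``n_nodes``.

    Simple: n(n-1)/2 undirected, n(n-1) directed.  Multigraphs add
    sum(m_i - 1) over the supplied per-dyad multiplicities (unobserved
    dyads have m_i = 1 and contribute nothing).
    """
    if n_nodes < 2:
        raise ValueError("no dyads exist below 2 nodes")
    base = n_nodes * (n_nodes - 1) if directed else n_nodes * (n_nodes - 1) // 2
    extra = 0
    if multiplicities is not None:
        extra = sum(max(int(m), 1) - 1 for m in multiplicities)
    return base + extra


def _zero_padded(weights: np.ndarray, denominator: int) -> np.ndarray:
    padded = np.zeros(denominator)
    padded[: len(weights)] = weights
    return padded


def subgroup_target(pattern: Pattern, table: AttributedDyadTable,
                    spec: QualitySpec) -> TargetValue:
    """t_P of a pattern under the spec's measure and metric.

    Subgraph-normalized measures sum the covered observed weights and
    divide by the possible-dyad count of the covered node set (plus
    multiplicities for the multi variants); balanced measures average over
    the pattern-compatible completed-graph slots.  The variance metric
    replaces the mean with the population variance of the zero-padded
    weight multiset over the same slots.
    """
    spec.check_compatible(table.directed, table.multi)
    if spec.measure in BALANCED_MEASURES:
        recs, nodes = extension(pattern, table, observed_only=False)
        denominator = len(recs)
        if denominator == 0:
            raise ValueError(f"no admissible dyads for pattern {pattern.render()!r}")
        weights = np.array([r.weight for r in recs])
        observed = sum(1 for r in recs if r.observed)
    else:
        recs, nodes = extension(pattern, table, observed_only=True)
        if len(nodes) < 2:
            raise ValueError(f"no admissible dyads for pattern {pattern.render()!r}")
        mults = None
        if spec.measure in ("qM", "qDM"):
            per_dyad: dict = {}
            for rec in table.records:
                if rec.observed and rec.source in nodes and rec.target in nodes:
                    key = (rec.source, rec.target)
                    per_dyad[key] = per_dyad.get(key, 0) + 1
            mults = per_dyad.values()
        denominator = possible_edges(len(nodes), table.directed, mults)
        weights = np.array([r.weight for r in recs])
        observed = len(recs)
    weight_sum = float(weights.sum())
    if spec.metric == "mean":
        t_p = weight_sum / denominator
    else:
        t_p = float(_zero_padded(weights, denominator).var(ddof=0))
    return TargetValue(t_p, denominator, weight_sum, len(nodes), observed)


def baseline_quality(t_p: float, t_0: float, n: int, a: float) -> float:
    """Classical size/deviation trade-off q_a = n^a (t_P - t_0).

    a = 0 is the gain function, a = 0.5 the simplified binomial.  Kept as a
    reference ranking; the dyadic measures above replace it here.
    """
    if not 0 <= a <= 1:
        raise ValueError("a must lie in [0, 1]")
    return float(n ** a * (t_p - t_0))


def evaluate(pattern: Pattern, table: AttributedDyadTable, graph,
             spec: QualitySpec, null_seed: int | None = None) -> SubgroupResult:
    """Full quality evaluation: target, null sampling, z, p.

    The null draws ``spec.r`` random slot sets of the target's denominator
    size from the measure's global zero-padded universe.  The p-value comes
    from the normal law when the Shapiro-Wilk gate passes at ``spec.alpha``,
    else from the add-one empirical rule.
    """
    target = subgroup_target(pattern, table, spec)
    universe = build_universe(graph, spec.measure)
    seed = spec.seed if null_seed is None else null_seed
    null = sample_null(universe, target.denominator, spec.r, seed, spec.metric)
    z = z_score(target.t_p, null)
    _, norm_p, passed = normality_check(null, spec.alpha)
    p = normal_p(z, spec.tail) if passed else empirical_p(target.t_p, null, spec.tail)
    return SubgroupResult(
        pattern=pattern,
        n_nodes=target.covered_nodes,
        n_edges=target.covered_edges,
        t_p=target.t_p,
        z=z,
        p=p,
        denominator=target.denominator,
        normality_passed=passed,
        normality_p=norm_p,
    )


# backwards-friendly alias matching the measure-as-function reading q(P) = Z(t_P)
quality = evaluate
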