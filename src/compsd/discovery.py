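"""Top-k exhaustive search over conjunctive dyad patterns.

Candidate patterns are all conjunctions of up to ``max_depth`` atomic
selectors over distinct attributes, drawn from the label domains observed
in the dyad table.  Every candidate passing the size constraints is scored
with the configured quality measure and the top k by the configured tail of
the z-score are returned.  The candidate spaces here are small (a handful
of attributes with 2-3 values), so exhaustive enumeration is exact and
cheap; z-score qualities admit no tight anti-monotone bound, so no pruning
beyond the size constraints is attempted.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterator

import pandas as pd

from .core import AttributedDyadTable, Pattern, Selector
from .nullmodel import DegenerateNullError
from .quality import QualitySpec, SubgroupResult, evaluate

logger = logging.getLogger("compsd")

TAILS = ("upper", "lower", "two_sided")


@dataclass(frozen=True)
class SearchConfig:
    """Search-space and ranking knobs."""

    spec: QualitySpec = field(default_factory=QualitySpec)
    top_k: int = 20
    max_depth: int = 3
    min_observed_edges: int = 1
    min_nodes: int = 2
    tail: str = "upper"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")


def enumerate_candidates(table: AttributedDyadTable, max_depth: int) -> Iterator[Pattern]:
    """All conjunctions of <= max_depth atomic selectors on distinct
    attributes, in canonical order, each exactly once."""
    domains = {attr: table.domain(attr) for attr in table.attributes}
    attrs = [a for a in table.attributes if domains[a]]
    for depth in range(1, max_depth + 1):
        for chosen in combinations(attrs, depth):
            for values in product(*(domains[a] for a in chosen)):
                yield Pattern(tuple(
                    Selector(a, frozenset([v])) for a, v in zip(chosen, values)
                ))


def pattern_seed(base_seed: int, pattern: Pattern) -> int:
    """Deterministic per-pattern null seed, independent of enumeration order."""
    digest = zlib.crc32(pattern.render().encode())
    return (base_seed * 1_000_003 + digest) % (2 ** 31)


def _rank_key(result: SubgroupResult, tail: str):
    primary = {"upper": -result.z, "lower": result.z, "two_sided": -abs(result.z)}[tail]
    return (primary, -abs(result.z), len(result.pattern), result.pattern.render())


def discover(table: AttributedDyadTable, graph, config: SearchConfig) -> list[SubgroupResult]:
    """Evaluate every candidate and return the top-k ranked results.

    Patterns with no admissible dyads, too few observed edges/nodes, or a
    degenerate null (zero spread) are skipped.  Ties break deterministically
    by (|z| desc, pattern length asc, rendered pattern asc).
    """
    config.spec.check_compatible(table.directed, table.multi)
    results: list[SubgroupResult] = []
    skipped = 0
    for pattern in enumerate_candidates(table, config.max_depth):
        try:
            res = evaluate(pattern, table, graph, config.spec,
                           null_seed=pattern_seed(config.spec.seed, pattern))
        except ValueError:
            skipped += 1
            continue
        except DegenerateNullError:
            logger.warning("degenerate null for pattern %s; skipped", pattern.render())
            skipped += 1
            continue
        if res.n_edges < config.min_observed_edges or res.n_nodes < config.min_nodes:
            skipped += 1
            continue
        results.append(res)
    if not results:
        logger.warning("no candidate pattern passed the constraints")
        return []
    results.sort(key=lambda r: _rank_key(r, config.tail))
    return results[: config.top_k]


def results_frame(results: list[SubgroupResult]) -> pd.DataFrame:
    """Ranked result table mirroring the usual report columns."""
    rows = []
    for rank, res in enumerate(results, start=1):
        row = {"rank": rank}
        row.update(res.as_row())
        rows.append(row)
    columns = ["rank", "pattern", "n_nodes", "n_edges", "t_P", "z", "p", "denominator"]
    return pd.DataFrame(rows, columns=columns)
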