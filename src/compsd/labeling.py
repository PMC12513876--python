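"""Compositional edge labels from node attributes.

Dyads inherit labels from the attribute values of their two endpoints:

* undirected (``eqneq``): per attribute, ``EQ`` when the endpoints share the
  value, else ``NEQ``;
* directed ``comparison``: nominal attributes become the ordered value pair
  ``(source, target)``; numeric attributes become ``same``/``higher``/
  ``lower`` describing the *target's* value relative to the source's;
* directed ``to_node`` / ``from_node``: copy the target's (resp. source's)
  attribute values onto the edge.

Node tables can additionally be enriched with network metrics (degree,
centralities, HITS hub/authority), discretized into equal-frequency bins so
they act as ordinary nominal attributes in the pattern search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import AttributedDyadTable, DyadRecord
from .graphs import InteractionGraph

logger = logging.getLogger("compsd")

UNDIRECTED_MODE = "eqneq"
DIRECTED_MODES = ("comparison", "to_node", "from_node")

#: bin labels for the common three-bin case; other k use b1..bk
_TERTILE_LABELS = ("low", "medium", "high")


@dataclass
class NodeTable:
    """id -> attribute map, with each attribute declared nominal or numeric."""

    rows: dict
    kinds: dict

    def __post_init__(self) -> None:
        self.rows = {str(k): dict(v) for k, v in self.rows.items()}
        for attr, kind in self.kinds.items():
            if kind not in ("nominal", "numeric"):
                raise ValueError(f"attribute {attr!r} has unknown kind {kind!r}")
        for node, attrs in self.rows.items():
            extra = set(attrs) - set(self.kinds)
            if extra:
                raise ValueError(f"node {node!r} has undeclared attributes {sorted(extra)}")

    @property
    def attributes(self) -> list[str]:
        return list(self.kinds)

    def __contains__(self, node) -> bool:
        return str(node) in self.rows

    def __getitem__(self, node) -> dict:
        key = str(node)
        if key not in self.rows:
            raise KeyError(f"unknown node id {node!r}")
        return self.rows[key]

    def with_attribute(self, name: str, values: dict, kind: str = "nominal") -> "NodeTable":
        rows = {n: {**attrs, name: values[n]} for n, attrs in self.rows.items()}
        kinds = {**self.kinds, name: kind}
        return NodeTable(rows, kinds)


@dataclass(frozen=True)
class LabelingScheme:
    """How node attributes map onto dyad labels."""

    mode: str = UNDIRECTED_MODE
    attributes: tuple | None = None

    def __post_init__(self) -> None:
        if self.mode not in (UNDIRECTED_MODE, *DIRECTED_MODES):
            raise ValueError(f"unknown labeling mode {self.mode!r}")
        if self.attributes is not None:
            object.__setattr__(self, "attributes", tuple(self.attributes))

    def select(self, nodes: NodeTable) -> list[str]:
        return list(self.attributes) if self.attributes is not None else nodes.attributes


def label_undirected(nodes: NodeTable, dyads: list[tuple],
                     attributes: list[str] | None = None) -> list[dict]:
    """EQ/NEQ labels per attribute for each unordered dyad."""
    attrs = attributes if attributes is not None else nodes.attributes
    out = []
    for a, b in dyads:
        va, vb = nodes[a], nodes[b]
        out.append({
            attr: "EQ" if va.get(attr) == vb.get(attr) else "NEQ"
            for attr in attrs
        })
    return out


def label_directed(nodes: NodeTable, dyads: list[tuple], scheme: LabelingScheme) -> list[dict]:
    """Comparison / to-node / from-node labels for each ordered dyad."""
    if scheme.mode not in DIRECTED_MODES:
        raise ValueError(f"scheme mode {scheme.mode!r} is not a directed mode")
    attrs = scheme.select(nodes)
    out = []
    for src, dst in dyads:
        vs, vt = nodes[src], nodes[dst]
        if scheme.mode == "to_node":
            out.append({attr: str(vt.get(attr)) for attr in attrs})
        elif scheme.mode == "from_node":
            out.append({attr: str(vs.get(attr)) for attr in attrs})
        else:  # comparison
            labels = {}
            for attr in attrs:
                a, b = vs.get(attr), vt.get(attr)
                if nodes.kinds[attr] == "numeric":
                    try:
                        fa, fb = float(a), float(b)
                    except (TypeError, ValueError) as err:
                        raise ValueError(
                            f"attribute {attr!r} is not ordered: {a!r} vs {b!r}"
                        ) from err
                    labels[attr] = "same" if fa == fb else ("higher" if fb > fa else "lower")
                else:
                    labels[attr] = f"({a},{b})"
            out.append(labels)
    return out


def discretize_equal_frequency(values, k: int, labels: tuple | None = None) -> list[str]:
    """Equal-frequency bin label per value; tie groups stay in one bin.

    The sorted positions are cut at multiples of n/k; a group of tied values
    takes the bin of its first sorted position (the lower bin), so bin sizes
    differ from n/k by at most the tie-group size.
    """
    values = list(values)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot cut {n} values into {k} bins")
    if labels is None:
        labels = _TERTILE_LABELS if k == 3 else tuple(f"b{i + 1}" for i in range(k))
    if len(labels) != k:
        raise ValueError("need one label per bin")
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    first_pos: dict = {}
    for pos, idx in enumerate(order):
        v = float(values[idx])
        first_pos.setdefault(v, pos)
    out = [None] * n
    for idx in range(n):
        pos = first_pos[float(values[idx])]
        out[idx] = labels[min(k - 1, pos * k // n)]
    return out


_UNDIRECTED_METRICS = ("degree", "betweenness", "closeness", "eigenvector")
_DIRECTED_METRICS = ("degree", "in_degree", "out_degree", "betweenness",
                     "closeness", "eigenvector", "authority", "hub")


def _metric_values(graph: InteractionGraph, metric: str) -> dict:
    g = graph.aggregate().to_networkx()
    if metric == "degree":
        return dict(g.degree())
    if metric == "in_degree":
        return dict(g.in_degree())
    if metric == "out_degree":
        return dict(g.out_degree())
    if metric == "betweenness":
        return nx.betweenness_centrality(g)
    if metric == "closeness":
        # Wasserman–Faust variant scales by component size: finite on
        # disconnected graphs without inventing infinite distances.
        return nx.closeness_centrality(g, wf_improved=True)
    if metric == "eigenvector":
        try:
            return nx.eigenvector_centrality(g, max_iter=1000, weight="weight")
        except nx.PowerIterationFailedConvergence as err:
            raise RuntimeError(
                "eigenvector centrality failed to converge within 1000 iterations"
            ) from err
    if metric in ("authority", "hub"):
        hubs, authorities = nx.hits(g, max_iter=1000)
        return authorities if metric == "authority" else hubs
    raise ValueError(f"unknown metric {metric!r}")


def enrich_with_metrics(graph: InteractionGraph, nodes: NodeTable,
                        metrics, k: int = 3) -> NodeTable:
    """Add discretized network metrics as nominal node attributes.

    Multigraphs are projected to their weight-aggregated simple graph before
    computing metrics (standard metric definitions assume simple graphs).
    """
    valid = _DIRECTED_METRICS if graph.directed else _UNDIRECTED_METRICS
    for metric in metrics:
        if metric not in valid:
            kind = "directed" if graph.directed else "undirected"
            raise ValueError(f"metric {metric!r} not valid for {kind} graphs")
    out = nodes
    ordered_nodes = [str(n) for n in graph.nodes]
    for metric in metrics:
        raw = {str(n): v for n, v in _metric_values(graph, metric).items()}
        values = [raw.get(n, 0.0) for n in ordered_nodes]
        bins = discretize_equal_frequency(values, k)
        out = out.with_attribute(metric, dict(zip(ordered_nodes, bins)), kind="nominal")
    return out


def build_dyad_table(graph: InteractionGraph, nodes: NodeTable,
                     scheme: LabelingScheme | None = None) -> AttributedDyadTable:
    """Completed edge-attributed database for a graph and its node attributes.

    Every dyad of the graph's node set gets at least one record: observed
    interactions keep their (multi-)edge weights; non-observed dyads become
    zero-weight slots so balanced measures and the null model can see the
    completed graph.
    """
    if scheme is None:
        scheme = LabelingScheme(UNDIRECTED_MODE if not graph.directed else "comparison")
    if graph.directed and scheme.mode == UNDIRECTED_MODE:
        raise ValueError("eqneq labeling requires an undirected graph")
    if not graph.directed and scheme.mode in DIRECTED_MODES:
        raise ValueError(f"{scheme.mode} labeling requires a directed graph")
    node_ids = [str(n) for n in graph.nodes]
    missing = [n for n in node_ids if n not in nodes]
    if missing:
        raise KeyError(f"nodes missing from node table: {missing}")
    if graph.directed:
        dyads = [(a, b) for a in node_ids for b in node_ids if a != b]
        labels = label_directed(nodes, dyads, scheme)
    else:
        dyads = []
        for i, a in enumerate(node_ids):
            for b in node_ids[i + 1:]:
                dyads.append(tuple(sorted((a, b), key=str)))
        labels = label_undirected(nodes, dyads, scheme.select(nodes))
    by_pair = graph.edges_by_pair()
    records = []
    for (a, b), lab in zip(dyads, labels):
        observed = by_pair.get((a, b), [])
        if observed:
            for idx, w in sorted(observed):
                records.append(DyadRecord(a, b, lab, w, observed=True, multi_index=idx))
        else:
            records.append(DyadRecord(a, b, lab, 0.0, observed=False))
    attrs = scheme.select(nodes)
    return AttributedDyadTable(records, attrs, directed=graph.directed, multi=graph.multi)
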