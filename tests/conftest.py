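"""Shared fixtures: tiny attributed networks with known structure."""

import numpy as np
import pytest

from compsd import (AttributedDyadTable, DyadRecord, InteractionGraph,
                    LabelingScheme, NodeTable, build_dyad_table)


@pytest.fixture
def two_f_two_m_nodes():
    """Four actors, two per gender — the smallest homophily-capable set."""
    return NodeTable(
        {
            "a": {"Gender": "F"},
            "b": {"Gender": "F"},
            "c": {"Gender": "M"},
            "d": {"Gender": "M"},
        },
        {"Gender": "nominal"},
    )


@pytest.fixture
def k4_graph():
    """Complete undirected simple graph on a,b,c,d with distinct weights."""
    edges = [
        ("a", "b", 1, 6.0),
        ("a", "c", 1, 1.0),
        ("a", "d", 1, 2.0),
        ("b", "c", 1, 3.0),
        ("b", "d", 1, 4.0),
        ("c", "d", 1, 5.0),
    ]
    return InteractionGraph(["a", "b", "c", "d"], edges, directed=False, multi=False)


@pytest.fixture
def k4_table(two_f_two_m_nodes, k4_graph):
    return build_dyad_table(k4_graph, two_f_two_m_nodes, LabelingScheme("eqneq"))


@pytest.fixture
def partial_graph():
    """Four nodes, F-F edge observed (weight 6), M-M dyad unobserved."""
    edges = [
        ("a", "b", 1, 6.0),
        ("a", "c", 1, 2.0),
        ("b", "d", 1, 4.0),
    ]
    return InteractionGraph(["a", "b", "c", "d"], edges, directed=False, multi=False)


@pytest.fixture
def partial_table(two_f_two_m_nodes, partial_graph):
    return build_dyad_table(partial_graph, two_f_two_m_nodes, LabelingScheme("eqneq"))


def random_simple_graph(rng, n, directed, density=0.6, max_weight=10.0):
    """Random simple graph as (node_ids, edges); weights uniform."""
    node_ids = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j or (not directed and j <= i):
                continue
            if rng.random() < density:
                edges.append((node_ids[i], node_ids[j], 1, float(rng.uniform(0.1, max_weight))))
    return node_ids, edges


def random_multi_graph(rng, n, directed, density=0.6, max_mult=3, max_weight=10.0):
    node_ids = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j or (not directed and j <= i):
                continue
            if rng.random() < density:
                m = int(rng.integers(1, max_mult + 1))
                for k in range(1, m + 1):
                    edges.append((node_ids[i], node_ids[j], k, float(rng.uniform(0.1, max_weight))))
    return node_ids, edges


def random_node_attrs(rng, node_ids, n_attrs=2, domain=("x", "y")):
    attrs = [f"A{k}" for k in range(n_attrs)]
    rows = {n: {a: str(rng.choice(domain)) for a in attrs} for n in node_ids}
    return NodeTable(rows, {a: "nominal" for a in attrs})
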