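"""Synthetic fixtures with known planted structure.

Two generators emulate the two data acquisition modes the pipeline
consumes, with planted effects the discovery stage should recover:

* :func:`generate_attributed_network` — an undirected attributed contact
  network whose interaction durations are exponentially distributed
  (face-to-face contact durations are heavy-tailed and right-skewed), with
  the dyads compatible with a *planted pattern* receiving an elevated mean
  (homophilous weight effect).

* :func:`generate_trajectories` — bounded 2-D random walks of agents in a
  square arena; with probability equal to the *attraction bias* an agent
  steps toward its nearest same-group peer instead of a random direction,
  which induces directed approach homophily the trajectory pipeline should
  surface.

Defaults mirror the scale of the reference settings: contact networks with
30 actors at density 0.34 (the conference contact-network density) and mean
contact duration 60 s; playground-like arenas of 40 x 40 length units with
18 agents, one step per time unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Pattern, covers, DyadRecord
from .graphs import InteractionGraph, SignOverlay, Trajectory
from .labeling import NodeTable, label_undirected

#: default attribute schema: binary gender plus a three-track nominal,
#: roughly matching the conference node attributes
DEFAULT_SCHEMA = {
    "Gender": (("F", "M"), (0.5, 0.5)),
    "Track": (("1", "2", "3"), (0.4, 0.3, 0.3)),
}


@dataclass(frozen=True)
class PlantedEffectSpec:
    """A homophilous weight effect to plant into a contact network."""

    pattern: Pattern = field(default_factory=lambda: Pattern.of(Gender="EQ"))
    effect: float = 30.0              # shift of the mean weight on planted dyads
    effect_kind: str = "additive"     # "additive" | "multiplicative"
    base_scale: float = 60.0          # exponential mean of background durations
    schema: dict = field(default_factory=lambda: dict(DEFAULT_SCHEMA))
    n_nodes: int = 30
    density: float = 0.34
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.effect_kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if self.base_scale <= 0:
            raise ValueError("base_scale must be positive")
        for attr, (values, probs) in self.schema.items():
            if len(values) != len(probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"bad marginal for attribute {attr!r}")


def _sample_nodes(spec: PlantedEffectSpec, rng: np.random.Generator) -> NodeTable:
    ids = [f"n{i:02d}" for i in range(spec.n_nodes)]
    rows = {}
    for node in ids:
        rows[node] = {
            attr: str(rng.choice(values, p=probs))
            for attr, (values, probs) in spec.schema.items()
        }
    kinds = {attr: "nominal" for attr in spec.schema}
    return NodeTable(rows, kinds)


def generate_attributed_network(spec: PlantedEffectSpec) -> tuple[NodeTable, InteractionGraph]:
    """Attributed contact network with a planted homophilous weight effect.

    Node attributes are sampled i.i.d. from the schema's marginals; each
    dyad is observed with probability ``density``; observed weights are
    exponential with mean ``base_scale``, and dyads whose EQ/NEQ labels are
    covered by the planted pattern get the effect applied (additive shift
    of the mean, or multiplicative scaling).
    """
    rng = np.random.default_rng(spec.seed)
    nodes = _sample_nodes(spec, rng)
    ids = sorted(nodes.rows)
    dyads = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    labels = label_undirected(nodes, dyads)
    edges = []
    for (a, b), lab in zip(dyads, labels):
        if rng.random() >= spec.density:
            continue
        w = rng.exponential(spec.base_scale)
        rec = DyadRecord(a, b, lab, 0.0, observed=False)
        if covers(spec.pattern, rec):
            if spec.effect_kind == "additive":
                w += spec.effect
            else:
                w *= spec.effect
        edges.append((a, b, 1, w))
    graph = InteractionGraph(ids, edges, directed=False, multi=False)
    return nodes, graph


def generate_trajectories(
    n_agents: int = 18,
    n_steps: int = 600,
    group_attribute: str = "Gender",
    groups: tuple = ("F", "M"),
    bias: float = 0.0,
    arena: float = 40.0,
    step_length: float = 1.0,
    seed: int = 0,
) -> tuple[NodeTable, Trajectory]:
    """Bounded random walks with group-biased approach behavior.

    Each step, with probability ``bias`` an agent moves toward its nearest
    same-group peer; otherwise it steps in a uniformly random direction.
    Positions are clipped to the [0, arena]^2 square; recorded velocities
    are the realized (post-clipping) displacements, with the last step
    copying the previous one.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    if n_steps < 2:
        raise ValueError("need at least 2 time steps")
    if not 0 <= bias <= 1:
        raise ValueError("bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"a{i:02d}" for i in range(n_agents)]
    group = [groups[i % len(groups)] for i in range(n_agents)]
    nodes = NodeTable(
        {ids[i]: {group_attribute: group[i]} for i in range(n_agents)},
        {group_attribute: "nominal"},
    )
    pos = rng.uniform(0, arena, size=(n_agents, 2))
    positions = np.empty((n_steps, n_agents, 2))
    group_idx = {g: np.array([i for i, gi in enumerate(group) if gi == g]) for g in set(group)}
    for t in range(n_steps):
        positions[t] = pos
        towards = rng.random(n_agents) < bias
        angles = rng.uniform(0, 2 * np.pi, n_agents)
        step = np.column_stack([np.cos(angles), np.sin(angles)]) * step_length
        for i in range(n_agents):
            if not towards[i]:
                continue
            peers = group_idx[group[i]]
            peers = peers[peers != i]
            if peers.size == 0:
                continue
            d = np.linalg.norm(pos[peers] - pos[i], axis=1)
            nearest = peers[int(np.argmin(d))]
            direction = pos[nearest] - pos[i]
            norm = np.linalg.norm(direction)
            if norm > 0:
                step[i] = direction / norm * min(step_length, norm)
        pos = np.clip(pos + step, 0.0, arena)
    vel = np.diff(positions, axis=0)
    vel = np.concatenate([vel, vel[-1:]], axis=0)  # last step copies previous
    frame = pd.DataFrame({
        "t": np.repeat(np.arange(n_steps), n_agents),
        "id": np.tile(np.array(ids, dtype=object), n_steps),
        "x": positions[:, :, 0].ravel(),
        "y": positions[:, :, 1].ravel(),
        "velX": vel[:, :, 0].ravel(),
        "velY": vel[:, :, 1].ravel(),
    })
    return nodes, Trajectory(frame)


def generate_sign_overlay(node_ids, dislike_count: int = 3, seed: int = 0) -> SignOverlay:
    """Each node nominates ``dislike_count`` distinct others as less liked."""
    node_ids = [str(n) for n in node_ids]
    if dislike_count >= len(node_ids):
        raise ValueError("dislike_count must be below the number of nodes")
    rng = np.random.default_rng(seed)
    entries = {}
    for node in node_ids:
        others = [n for n in node_ids if n != node]
        picks = rng.choice(len(others), size=dislike_count, replace=False)
        for k in picks:
            entries[(node, others[int(k)])] = 1
    return SignOverlay(entries, semantics="negative")
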