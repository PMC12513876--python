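"""Interaction-graph construction.

Two acquisition modes are supported:

* **Face-to-face contact lists** (RFID-style: ``idA, idB, duration``) become
  undirected graphs — either simple (durations summed per pair) or multi
  (one edge per contact with its own duration).

* **Movement trajectories** (``t, id, x, y, velX, velY``) become directed
  graphs via an approach rule: at each time step actor *i* approaches actor
  *j* when their distance is within ``maxdist`` and the cosine between the
  displacement vector r_ij = (x_j - x_i, y_j - y_i) and i's velocity is
  strictly positive.  The simple digraph counts approach steps per ordered
  pair; the multidigraph keeps one edge per maximal uninterrupted run of
  approach steps, weighted by the run length.

A sign overlay (e.g. "less liked" nominations) multiplies edge weights
element-wise; an absent entry means sign 0 ("unknown"), never "opposite".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger("compsd")


@dataclass
class ContactList:
    """Rows of (idA, idB, duration[, start]); duration > 0 and idA != idB."""

    rows: list[tuple]

    def __post_init__(self) -> None:
        for row in self.rows:
            a, b, dur = row[0], row[1], row[2]
            if a == b:
                raise ValueError(f"contact of {a!r} with itself")
            if dur <= 0:
                raise ValueError(f"non-positive contact duration {dur} for ({a},{b})")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Trajectory:
    """Per-step positions (and velocities) of every actor.

    Backed by a DataFrame with columns t, id, x, y and optionally
    velX, velY; (t, id) pairs are unique.
    """

    frame: pd.DataFrame

    REQUIRED = ("t", "id", "x", "y")
    VELOCITY = ("velX", "velY")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trajectory missing columns {missing}")
        if self.frame.duplicated(subset=["t", "id"]).any():
            dup = self.frame[self.frame.duplicated(subset=["t", "id"])].iloc[0]
            raise ValueError(f"duplicate trajectory row (t={dup['t']}, id={dup['id']})")
        self.frame = self.frame.sort_values(["t", "id"], kind="stable").reset_index(drop=True)

    @property
    def has_velocities(self) -> bool:
        return all(c in self.frame.columns for c in self.VELOCITY)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["t"].unique())

    @property
    def actor_ids(self) -> list:
        return sorted(self.frame["id"].unique().tolist())


@dataclass
class InteractionGraph:
    """Weighted interaction graph with explicit directed/multi flags.

    Edges are (source, target, multi_index, weight) tuples; simple graphs
    keep exactly one edge (multi_index 1) per (ordered) pair.  Undirected
    edges are stored with the canonical node order.
    """

    nodes: list
    edges: list[tuple]
    directed: bool = False
    multi: bool = False

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen = set()
        canon = []
        for src, dst, idx, w in self.edges:
            if src == dst:
                raise ValueError(f"self-loop on {src!r}")
            if w < 0:
                raise ValueError("edge weight must be non-negative")
            if src not in node_set or dst not in node_set:
                raise ValueError(f"edge ({src},{dst}) references unknown node")
            if not self.directed and str(src) > str(dst):
                src, dst = dst, src
            key = (src, dst, idx)
            if key in seen:
                raise ValueError(f"duplicate edge slot {key}")
            if not self.multi and idx != 1:
                raise ValueError("simple graph edges must have multi_index 1")
            seen.add(key)
            canon.append((src, dst, idx, float(w)))
        if not self.multi:
            pairs = {(s, d) for s, d, _, _ in canon}
            if len(pairs) != len(canon):
                raise ValueError("simple graph has parallel edges")
        self.edges = canon

    def pair_key(self, src, dst) -> tuple:
        if self.directed or str(src) <= str(dst):
            return (src, dst)
        return (dst, src)

    def weight_by_pair(self) -> dict:
        """Aggregated weight per (ordered / canonical unordered) pair."""
        agg: dict = {}
        for src, dst, _, w in self.edges:
            key = (src, dst)
            agg[key] = agg.get(key, 0.0) + w
        return agg

    def multiplicity_by_pair(self) -> dict:
        mult: dict = {}
        for src, dst, _, _ in self.edges:
            key = (src, dst)
            mult[key] = mult.get(key, 0) + 1
        return mult

    def edges_by_pair(self) -> dict:
        out: dict = {}
        for src, dst, idx, w in self.edges:
            out.setdefault((src, dst), []).append((idx, w))
        return out

    def aggregate(self) -> "InteractionGraph":
        """Weight-aggregated simple projection (sums parallel edges)."""
        agg = self.weight_by_pair()
        edges = [(s, d, 1, w) for (s, d), w in sorted(agg.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))]
        return InteractionGraph(list(self.nodes), edges, directed=self.directed, multi=False)

    def to_networkx(self):
        import networkx as nx

        cls = {
            (False, False): nx.Graph,
            (False, True): nx.MultiGraph,
            (True, False): nx.DiGraph,
            (True, True): nx.MultiDiGraph,
        }[(self.directed, self.multi)]
        g = cls()
        g.add_nodes_from(self.nodes)
        for src, dst, idx, w in self.edges:
            if self.multi:
                g.add_edge(src, dst, key=idx, weight=w)
            else:
                g.add_edge(src, dst, weight=w)
        return g


@dataclass
class SignOverlay:
    """{0,1}-signed relation over ordered pairs; semantics says which tie
    kind a weight of 1 encodes ("positive" or "negative").  A missing pair
    means sign 0: no information, not the opposite tie."""

    entries: dict
    semantics: str = "negative"

    def __post_init__(self) -> None:
        clean = {}
        for (src, dst), sign in self.entries.items():
            if sign not in (0, 1):
                raise ValueError(f"sign must be 0/1, got {sign!r} for ({src},{dst})")
            if src == dst:
                raise ValueError(f"self-sign on {src!r}")
            clean[(src, dst)] = int(sign)
        self.entries = clean
        if self.semantics not in ("positive", "negative"):
            raise ValueError("semantics must be 'positive' or 'negative'")

    def sign(self, src, dst, directed: bool = True) -> int:
        if directed:
            return self.entries.get((src, dst), 0)
        return max(self.entries.get((src, dst), 0), self.entries.get((dst, src), 0))


# ---------------------------------------------------------------------------
# Face-to-face contact graphs
# ---------------------------------------------------------------------------

def build_f2f_graph(contacts: ContactList, multi: bool = False,
                    nodes: list | None = None) -> InteractionGraph:
    """Undirected contact graph: aggregated (simple) or per-contact (multi)."""
    node_order: dict = {}
    for n in nodes or []:
        node_order.setdefault(n)
    for row in contacts.rows:
        node_order.setdefault(row[0])
        node_order.setdefault(row[1])
    if multi:
        counter: dict = {}
        edges = []
        for row in contacts.rows:
            a, b = sorted((row[0], row[1]), key=str)
            counter[(a, b)] = counter.get((a, b), 0) + 1
            edges.append((a, b, counter[(a, b)], float(row[2])))
    else:
        agg: dict = {}
        for row in contacts.rows:
            a, b = sorted((row[0], row[1]), key=str)
            agg[(a, b)] = agg.get((a, b), 0.0) + float(row[2])
        edges = [(a, b, 1, w) for (a, b), w in sorted(agg.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))]
    return InteractionGraph(list(node_order), edges, directed=False, multi=multi)


def contact_summary(n_participants: int, n_unique_contacts: int) -> dict:
    """Mean degree and density of the undirected simple contact graph.

    With |V| participants and |U| unique contact pairs: mean degree
    2|U|/|V|, density |U| / C(|V|, 2).
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    v, u = n_participants, n_unique_contacts
    return {
        "mean_degree": 2.0 * u / v,
        "density": u / (v * (v - 1) / 2.0),
    }


# ---------------------------------------------------------------------------
# Trajectory-derived digraphs
# ---------------------------------------------------------------------------

def derive_velocities(traj: Trajectory) -> Trajectory:
    """Forward-difference velocities per actor; the last step copies the
    previous value.  A single-step actor gets zero velocity (warned)."""
    frame = traj.frame.copy()
    vx = np.zeros(len(frame))
    vy = np.zeros(len(frame))
    for _, idx in frame.groupby("id", sort=False).groups.items():
        idx = np.asarray(idx)
        x = frame.loc[idx, "x"].to_numpy(float)
        y = frame.loc[idx, "y"].to_numpy(float)
        if len(idx) < 2:
            logger.warning("actor %r has a single step; velocity set to zero",
                           frame.loc[idx[0], "id"])
            continue
        vx[idx[:-1]] = np.diff(x)
        vy[idx[:-1]] = np.diff(y)
        vx[idx[-1]] = vx[idx[-2]]
        vy[idx[-1]] = vy[idx[-2]]
    frame["velX"] = vx
    frame["velY"] = vy
    return Trajectory(frame)


def approach_events(frame: pd.DataFrame, maxdist: float) -> set[tuple]:
    """Ordered approach pairs at one time step.

    (i, j) fires iff d_ij <= maxdist and cos(r_ij, vel_i) > 0.  Coincident
    positions or a zero velocity make the cosine undefined -> no event.
    """
    if maxdist <= 0:
        raise ValueError("maxdist must be positive")
    ids = frame["id"].to_list()
    pos = frame[["x", "y"]].to_numpy(float)
    vel = frame[["velX", "velY"]].to_numpy(float)
    n = len(ids)
    if n < 2:
        return set()
    # distance matrix once per step
    diff = pos[None, :, :] - pos[:, None, :]          # r[i, j] = pos_j - pos_i
    dist = np.sqrt((diff ** 2).sum(axis=2))
    speed = np.sqrt((vel ** 2).sum(axis=1))
    dots = (diff * vel[:, None, :]).sum(axis=2)       # r_ij . vel_i
    ok = (dist <= maxdist) & (dist > 0) & (speed[:, None] > 0) & (dots > 0)
    np.fill_diagonal(ok, False)
    return {(ids[i], ids[j]) for i, j in zip(*np.nonzero(ok))}


def _events_per_step(traj: Trajectory, maxdist: float) -> dict:
    """time -> set of ordered approach pairs."""
    if not traj.has_velocities:
        raise ValueError("trajectory lacks velocities; call derive_velocities first")
    out = {}
    for t, grp in traj.frame.groupby("t", sort=True):
        out[t] = approach_events(grp, maxdist)
    return out


def build_digraph(traj: Trajectory, maxdist: float) -> InteractionGraph:
    """Simple digraph; w_ij = number of time steps with an i->j approach."""
    if traj.frame.empty:
        return InteractionGraph([], [], directed=True, multi=False)
    weights: dict = {}
    for _, events in _events_per_step(traj, maxdist).items():
        for pair in events:
            weights[pair] = weights.get(pair, 0.0) + 1.0
    edges = [(i, j, 1, w) for (i, j), w in sorted(weights.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))]
    return InteractionGraph(traj.actor_ids, edges, directed=True, multi=False)


def build_multidigraph(traj: Trajectory, maxdist: float) -> InteractionGraph:
    """Multidigraph; one edge per maximal uninterrupted run of i->j
    approaches, weighted by the run length.

    "Uninterrupted" means the approach also held at the immediately
    preceding recorded time step; a step at which either actor is absent
    produces no event there and hence breaks the run.
    """
    if traj.frame.empty:
        return InteractionGraph([], [], directed=True, multi=True)
    per_step = _events_per_step(traj, maxdist)
    # runs are segmented on the global recorded time sequence: a step at
    # which either actor is absent produces no event and breaks the run
    index_of = {t: k for k, t in enumerate(sorted(per_step))}
    event_times: dict = {}
    for t, events in per_step.items():
        for pair in events:
            event_times.setdefault(pair, []).append(t)
    edges = []
    for (i, j), times in sorted(event_times.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        run_len = 0
        prev_idx = None
        multi_index = 0
        for t in sorted(times):
            k = index_of[t]
            if prev_idx is not None and k == prev_idx + 1:
                run_len += 1
            else:
                if run_len:
                    multi_index += 1
                    edges.append((i, j, multi_index, float(run_len)))
                run_len = 1
            prev_idx = k
        if run_len:
            multi_index += 1
            edges.append((i, j, multi_index, float(run_len)))
    return InteractionGraph(traj.actor_ids, edges, directed=True, multi=True)


# ---------------------------------------------------------------------------
# Signed graphs
# ---------------------------------------------------------------------------

def apply_sign(graph: InteractionGraph, overlay: SignOverlay) -> InteractionGraph:
    """Replace w(e) by w(e) * sign(e); absent overlay entries are sign 0."""
    known = {n for pair in overlay.entries for n in pair}
    unknown = known - set(graph.nodes)
    if unknown:
        raise ValueError(f"overlay references unknown nodes {sorted(unknown, key=str)}")
    edges = [
        (src, dst, idx, w * overlay.sign(src, dst, directed=graph.directed))
        for src, dst, idx, w in graph.edges
    ]
    return InteractionGraph(list(graph.nodes), edges, directed=graph.directed,
                            multi=graph.multi)
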