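"""Delimited-text readers/writers, run configuration, and the pipeline.

All containers round-trip through plain TSV/CSV:

* node table: header row with an ``id`` column; attribute kinds declared in
  the config (or inferred: a column that parses as numbers is numeric);
* contact list: ``idA, idB, duration[, start]``;
* trajectory: ``t, id, x, y[, velX, velY]`` (velocities derived when absent);
* sign overlay: ``src, dst, sign``;
* graph: edge list ``source, target, multi_index, weight`` plus a node list;
* dyad table: ``source, target, multi_index, weight, observed, label:<attr>...``;
* result table: ``rank, pattern, n_nodes, n_edges, t_P, z, p, denominator``.

``run_pipeline`` orchestrates build -> label -> (enrich) -> discover and
writes the ranked table plus a YAML manifest sufficient to reproduce the
run (config echo, seed, r, normality outcomes).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import AttributedDyadTable, DyadRecord
from .discovery import SearchConfig, discover, results_frame
from .graphs import (ContactList, InteractionGraph, SignOverlay, Trajectory,
                     apply_sign, build_digraph, build_f2f_graph,
                     build_multidigraph, derive_velocities)
from .labeling import LabelingScheme, NodeTable, build_dyad_table, enrich_with_metrics
from .quality import QualitySpec

logger = logging.getLogger("compsd")

SEP = "\t"


class InputError(ValueError):
    """Malformed input file; message cites the offending line where known."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_frame(path, required: tuple, what: str) -> pd.DataFrame:
    frame = None
    for sep in (SEP, ",", None):  # sniffing fails on single-column files
        try:
            if sep is None:
                candidate = pd.read_csv(path, sep=None, engine="python")
            else:
                candidate = pd.read_csv(path, sep=sep, float_precision="round_trip")
        except Exception:
            continue
        if frame is None or len(candidate.columns) > len(frame.columns):
            frame = candidate
        if all(c in candidate.columns for c in required):
            frame = candidate
            break
    if frame is None:
        raise InputError(f"{what} {path}: unreadable file")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{what} {path}: missing columns {missing}")
    return frame


def read_node_table(path, kinds: dict | None = None) -> NodeTable:
    frame = _read_frame(path, ("id",), "node table")
    if frame["id"].duplicated().any():
        dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
        raise InputError(f"node table {path}: duplicate id {dup!r}")
    attrs = [c for c in frame.columns if c != "id"]
    if kinds is None:
        kinds = {
            a: "numeric" if pd.api.types.is_numeric_dtype(frame[a]) else "nominal"
            for a in attrs
        }
    rows = {
        str(rec["id"]): {
            a: (str(rec[a]) if kinds.get(a) == "nominal" else rec[a]) for a in attrs
        }
        for rec in frame.to_dict("records")
    }
    logger.info("read %d nodes from %s", len(rows), path)
    return NodeTable(rows, kinds)


def write_node_table(nodes: NodeTable, path) -> None:
    rows = [{"id": n, **attrs} for n, attrs in nodes.rows.items()]
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_contacts(path) -> ContactList:
    frame = _read_frame(path, ("idA", "idB", "duration"), "contact list")
    rows = []
    for i, rec in enumerate(frame.to_dict("records"), start=2):
        try:
            dur = float(rec["duration"])
        except (TypeError, ValueError):
            raise InputError(f"contact list {path} line {i}: bad duration {rec['duration']!r}")
        row = (str(rec["idA"]), str(rec["idB"]), dur)
        if "start" in frame.columns:
            row = (*row, rec["start"])
        rows.append(row)
    logger.info("read %d contacts from %s", len(rows), path)
    return ContactList(rows)


def write_contacts(contacts: ContactList, path) -> None:
    cols = ["idA", "idB", "duration"] + (["start"] if contacts.rows and len(contacts.rows[0]) > 3 else [])
    pd.DataFrame(contacts.rows, columns=cols).to_csv(path, sep=SEP, index=False)


def read_trajectory(path) -> Trajectory:
    frame = _read_frame(path, Trajectory.REQUIRED, "trajectory")
    for col in ("x", "y"):
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise InputError(f"trajectory {path} line {line}: non-numeric {col}")
        frame[col] = pd.to_numeric(frame[col])
    dup = frame.duplicated(subset=["t", "id"])
    if dup.any():
        raise InputError(f"trajectory {path} line {int(dup.idxmax()) + 2}: duplicate (t,id)")
    frame["id"] = frame["id"].astype(str)
    logger.info("read %d trajectory rows (%d actors) from %s",
                len(frame), frame["id"].nunique(), path)
    return Trajectory(frame)


def write_trajectory(traj: Trajectory, path) -> None:
    traj.frame.to_csv(path, sep=SEP, index=False)


def read_sign_overlay(path, semantics: str = "negative") -> SignOverlay:
    frame = _read_frame(path, ("src", "dst", "sign"), "sign overlay")
    entries = {
        (str(rec["src"]), str(rec["dst"])): int(rec["sign"])
        for rec in frame.to_dict("records")
    }
    return SignOverlay(entries, semantics=semantics)


def write_sign_overlay(overlay: SignOverlay, path) -> None:
    rows = [{"src": s, "dst": d, "sign": v} for (s, d), v in overlay.entries.items()]
    pd.DataFrame(rows, columns=["src", "dst", "sign"]).to_csv(path, sep=SEP, index=False)


def write_graph(graph: InteractionGraph, edges_path, nodes_path=None) -> None:
    pd.DataFrame(graph.edges, columns=["source", "target", "multi_index", "weight"]) \
        .to_csv(edges_path, sep=SEP, index=False)
    if nodes_path is not None:
        pd.DataFrame({"id": graph.nodes}).to_csv(nodes_path, sep=SEP, index=False)


def read_graph(edges_path, nodes_path=None, directed: bool = False,
               multi: bool = False) -> InteractionGraph:
    frame = _read_frame(edges_path, ("source", "target", "multi_index", "weight"), "edge list")
    edges = [
        (str(r["source"]), str(r["target"]), int(r["multi_index"]), float(r["weight"]))
        for r in frame.to_dict("records")
    ]
    if nodes_path is not None:
        nodes = [str(n) for n in _read_frame(nodes_path, ("id",), "node list")["id"]]
    else:
        nodes = sorted({n for e in edges for n in e[:2]})
    return InteractionGraph(nodes, edges, directed=directed, multi=multi)


def write_dyad_table(table: AttributedDyadTable, path) -> None:
    table.frame.to_csv(path, sep=SEP, index=False)


def read_dyad_table(path, directed: bool = False, multi: bool = False) -> AttributedDyadTable:
    frame = _read_frame(path, ("source", "target", "multi_index", "weight", "observed"),
                        "dyad table")
    attrs = [c[len("label:"):] for c in frame.columns if c.startswith("label:")]
    records = []
    for rec in frame.to_dict("records"):
        labels = {a: rec[f"label:{a}"] for a in attrs if pd.notna(rec[f"label:{a}"])}
        records.append(DyadRecord(
            str(rec["source"]), str(rec["target"]), labels,
            float(rec["weight"]), observed=bool(rec["observed"]),
            multi_index=int(rec["multi_index"]),
        ))
    return AttributedDyadTable(records, attrs, directed=directed, multi=multi)


def write_results(results, path) -> None:
    results_frame(results).to_csv(path, sep=SEP, index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one end-to-end run needs; cross-field checked up front."""

    nodes_path: str
    mode: str = "f2f"                     # "f2f" | "trajectory"
    contacts_path: str | None = None
    trajectory_path: str | None = None
    sign_path: str | None = None
    sign_semantics: str = "negative"
    multi: bool = False
    maxdist: float | None = None          # mandatory for trajectory mode
    scheme: str = "eqneq"
    attributes: tuple | None = None
    metrics: tuple = ()
    bins: int = 3
    measure: str = "qS"
    metric: str = "mean"
    r: int = 1000
    alpha: float = 0.05
    top_k: int = 20
    max_depth: int = 3
    min_observed_edges: int = 1
    min_nodes: int = 2
    tail: str = "upper"
    seed: int = 0
    output_path: str = "results.tsv"
    log_level: str = "INFO"

    @property
    def directed(self) -> bool:
        return self.mode == "trajectory"

    def validate(self) -> None:
        if self.mode not in ("f2f", "trajectory"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "f2f" and not self.contacts_path:
            raise ValueError("f2f mode needs contacts_path")
        if self.mode == "trajectory":
            if not self.trajectory_path:
                raise ValueError("trajectory mode needs trajectory_path")
            if self.maxdist is None or self.maxdist <= 0:
                raise ValueError("trajectory mode needs a positive maxdist")
        scheme = LabelingScheme(self.scheme, self.attributes)
        if self.directed and scheme.mode == "eqneq":
            raise ValueError("eqneq labeling is undirected; pick a directed scheme")
        if not self.directed and scheme.mode != "eqneq":
            raise ValueError(f"{scheme.mode} labeling needs trajectory (directed) mode")
        # measure/graph compatibility, before any I/O
        self.quality_spec().check_compatible(self.directed, self.multi)
        SearchConfig(spec=self.quality_spec(), top_k=self.top_k,
                     max_depth=self.max_depth, tail=self.tail)

    def quality_spec(self) -> QualitySpec:
        return QualitySpec(measure=self.measure, metric=self.metric, r=self.r,
                           seed=self.seed, alpha=self.alpha, tail="two_sided")

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            spec=self.quality_spec(), top_k=self.top_k, max_depth=self.max_depth,
            min_observed_edges=self.min_observed_edges, min_nodes=self.min_nodes,
            tail=self.tail,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys {sorted(extra)}")
        for key in ("attributes", "metrics"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("attributes", "metrics"):
            if out[key] is not None:
                out[key] = list(out[key])
        return out


def read_inputs(config: RunConfig):
    """Typed, validated containers for a run (velocities derived if absent)."""
    nodes = read_node_table(config.nodes_path)
    if config.mode == "f2f":
        data = read_contacts(config.contacts_path)
    else:
        data = read_trajectory(config.trajectory_path)
        if not data.has_velocities:
            logger.info("trajectory lacks velocities; deriving by forward difference")
            data = derive_velocities(data)
    overlay = None
    if config.sign_path:
        overlay = read_sign_overlay(config.sign_path, config.sign_semantics)
    return nodes, data, overlay


def build_graph(config: RunConfig, data) -> InteractionGraph:
    if config.mode == "f2f":
        return build_f2f_graph(data, multi=config.multi)
    if config.multi:
        return build_multidigraph(data, config.maxdist)
    return build_digraph(data, config.maxdist)


def run_pipeline(config: RunConfig) -> Path:
    """build -> label -> (enrich) -> discover; writes results + manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    stage = "read inputs"
    try:
        nodes, data, overlay = read_inputs(config)
        stage = "build graph"
        graph = build_graph(config, data)
        if overlay is not None:
            graph = apply_sign(graph, overlay)
        stage = "enrich"
        if config.metrics:
            nodes = enrich_with_metrics(graph, nodes, config.metrics, k=config.bins)
        stage = "label dyads"
        scheme = LabelingScheme(config.scheme, config.attributes)
        table = build_dyad_table(graph, nodes, scheme)
        stage = "discover"
        results = discover(table, graph, config.search_config())
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    out = Path(config.output_path)
    write_results(results, out)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "r": config.r,
        "n_results": len(results),
        "normality": [
            {"pattern": res.pattern.render(), "passed": res.normality_passed,
             "p": round(res.normality_p, 6)}
            for res in results
        ],
    }
    out.with_suffix(out.suffix + ".manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False))
    logger.info("wrote %d results to %s", len(results), out)
    return out
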