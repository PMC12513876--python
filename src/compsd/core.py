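"""Pattern/selector formalism over edge-attributed dyad tables.

Compositional subgroup discovery works on a database of *dyads*: every
(ordered or unordered) pair of actors is a slot of the interaction graph,
carrying a label map derived from the two actors' attributes and a
non-negative interaction weight (e.g. seconds of face-to-face contact).
Slots without an observed interaction are kept with weight zero so that the
"completed" graph — the universe the balanced quality measures and the
sampling null model operate on — is materialized explicitly.

A *selector* restricts one label attribute to a set of admissible values; a
*pattern* is a conjunction of selectors (at most one per attribute).  The
*extension* of a pattern is the set of dyad records it covers, either the
observed ones only (subgraph-normalized measures) or every completed-graph
slot (balanced measures).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger("compsd")

#: What to do when a pattern references an attribute missing from a record's
#: label map: "exclude" treats the record as not covered (and logs once),
#: "strict" raises.  The paper's data has no missing labels; real data may.
MissingPolicy = Literal["exclude", "strict"]
DEFAULT_MISSING_POLICY: MissingPolicy = "exclude"


class PatternParseError(ValueError):
    """Raised for malformed pattern text or duplicate attributes."""


@dataclass(frozen=True)
class Selector:
    """An attribute/value-set condition on dyad labels.

    A singleton value set is an *atomic* selector (``Gender=EQ``); a larger
    set expresses an internal disjunction (``track=1,2``).
    """

    attribute: str
    values: frozenset

    def __post_init__(self) -> None:
        if not self.attribute:
            raise ValueError("selector needs a non-empty attribute name")
        object.__setattr__(self, "values", frozenset(str(v) for v in self.values))
        if not self.values:
            raise ValueError(f"selector on {self.attribute!r} has an empty value set")

    @property
    def atomic(self) -> bool:
        return len(self.values) == 1

    def matches(self, value) -> bool:
        return str(value) in self.values

    def render(self) -> str:
        return f"{self.attribute}={','.join(sorted(self.values))}"


@dataclass(frozen=True)
class Pattern:
    """A conjunction of selectors; the empty conjunction is universal.

    Selectors are canonically ordered by attribute name so that equal
    conjunctions compare (and render) identically regardless of the order
    they were supplied in.
    """

    selectors: tuple[Selector, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.selectors, key=lambda s: s.attribute))
        attrs = [s.attribute for s in ordered]
        if len(set(attrs)) != len(attrs):
            dup = next(a for a in attrs if attrs.count(a) > 1)
            raise PatternParseError(f"duplicate attribute in pattern: {dup!r}")
        object.__setattr__(self, "selectors", ordered)

    @classmethod
    def of(cls, **conditions) -> "Pattern":
        """Build a pattern from keyword conditions.

        Values may be scalars (atomic selector) or iterables of values.
        """
        sels = []
        for attr, val in conditions.items():
            if isinstance(val, (str, bytes)) or not isinstance(val, Iterable):
                val = [val]
            sels.append(Selector(attr, frozenset(val)))
        return cls(tuple(sels))

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(s.attribute for s in self.selectors)

    @property
    def is_universal(self) -> bool:
        return not self.selectors

    def __len__(self) -> int:
        return len(self.selectors)

    def render(self) -> str:
        return " AND ".join(s.render() for s in self.selectors)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render() or "<universal>"


@dataclass(frozen=True)
class DyadRecord:
    """One slot of the (completed) interaction graph.

    ``observed`` distinguishes a real interaction from a zero-weight
    completed-graph slot.  Multigraph tables carry one record per
    multi-edge, numbered by ``multi_index``.
    """

    source: str
    target: str
    labels: dict
    weight: float
    observed: bool = True
    multi_index: int = 1

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop dyad on node {self.source!r}")
        if self.weight < 0:
            raise ValueError("dyad weight must be non-negative")
        if not self.observed and (self.weight != 0 or self.multi_index != 1):
            raise ValueError("unobserved slots must have weight 0 and multi_index 1")
        object.__setattr__(
            self, "labels", {str(k): str(v) for k, v in self.labels.items()}
        )


@dataclass
class AttributedDyadTable:
    """The edge-attributed database: dyad records plus their attribute schema."""

    records: list[DyadRecord]
    attributes: list[str]
    directed: bool = False
    multi: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            extra = set(rec.labels) - set(self.attributes)
            if extra:
                raise ValueError(f"record labels {sorted(extra)} not in declared attributes")
            pair = (rec.source, rec.target) if self.directed else tuple(
                sorted((rec.source, rec.target))
            )
            key = (*pair, rec.multi_index)
            if key in seen:
                raise ValueError(f"duplicate dyad slot {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def nodes(self) -> list[str]:
        out: dict[str, None] = {}
        for rec in self.records:
            out.setdefault(rec.source)
            out.setdefault(rec.target)
        return list(out)

    def domain(self, attribute: str) -> list[str]:
        """Observed label domain of one attribute, sorted."""
        if attribute not in self.attributes:
            raise KeyError(attribute)
        return sorted({rec.labels[attribute] for rec in self.records if attribute in rec.labels})

    @cached_property
    def frame(self) -> pd.DataFrame:
        """Columnar view used by the vectorized coverage path."""
        rows = [
            {
                "source": r.source,
                "target": r.target,
                "multi_index": r.multi_index,
                "weight": r.weight,
                "observed": r.observed,
                **{f"label:{a}": r.labels.get(a) for a in self.attributes},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def covers(
    pattern: Pattern,
    record: DyadRecord,
    missing: MissingPolicy = DEFAULT_MISSING_POLICY,
) -> bool:
    """True iff every selector admits the record's label for its attribute.

    The universal pattern covers everything.  A label missing from the
    record is handled per ``missing``: "exclude" -> not covered, "strict"
    -> KeyError.
    """
    for sel in pattern.selectors:
        if sel.attribute not in record.labels:
            if missing == "strict":
                raise KeyError(
                    f"record ({record.source},{record.target}) lacks label "
                    f"{sel.attribute!r}"
                )
            logger.debug(
                "excluding dyad (%s,%s): missing label %r",
                record.source, record.target, sel.attribute,
            )
            return False
        if not sel.matches(record.labels[sel.attribute]):
            return False
    return True


def coverage_mask(
    pattern: Pattern,
    table: AttributedDyadTable,
    missing: MissingPolicy = DEFAULT_MISSING_POLICY,
):
    """Vectorized boolean coverage over ``table.frame`` (same semantics as covers)."""
    frame = table.frame
    mask = pd.Series(True, index=frame.index)
    for sel in pattern.selectors:
        col = frame[f"label:{sel.attribute}"]
        hit = col.isin(sel.values)
        if missing == "strict" and col.isna().any():
            raise KeyError(f"records lack label {sel.attribute!r}")
        mask &= hit.fillna(False) if col.isna().any() else hit
    return mask.to_numpy()


def extension(
    pattern: Pattern,
    table: AttributedDyadTable,
    observed_only: bool = True,
    missing: MissingPolicy = DEFAULT_MISSING_POLICY,
) -> tuple[list[DyadRecord], set]:
    """Covered dyad records and the node set they induce.

    ``observed_only=True`` yields :math:`E_P` (observed interactions covered
    by the pattern); ``False`` yields the balanced slot set — every
    completed-graph slot compatible with the pattern
    (:math:`E_{CP}/E_{SP}/E_{MP}` depending on the table's flags).
    """
    if not table.records:
        raise ValueError("empty dyad table")
    recs = [
        r
        for r in table.records
        if (r.observed or not observed_only) and covers(pattern, r, missing)
    ]
    nodes: set = set()
    for r in recs:
        nodes.add(r.source)
        nodes.add(r.target)
    return recs, nodes


_SELECTOR_RE = re.compile(r"^([^=]+)=(.+)$")


def _split_values(text: str) -> list[str]:
    """Split a value list on top-level commas (commas inside (...) are literal)."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def parse_pattern(text: str) -> Pattern:
    """Parse ``attr=val[,val...](" AND " attr=val...)*`` into a Pattern.

    The empty string parses to the universal pattern.  Round-trips through
    :meth:`Pattern.render`.
    """
    text = text.strip()
    if not text:
        return Pattern()
    selectors = []
    for token in text.split(" AND "):
        token = token.strip()
        m = _SELECTOR_RE.match(token)
        if not m:
            raise PatternParseError(f"malformed selector: {token!r}")
        attr, values = m.group(1).strip(), _split_values(m.group(2).strip())
        if any(not v for v in values):
            raise PatternParseError(f"empty value in selector: {token!r}")
        selectors.append(Selector(attr, frozenset(values)))
    return Pattern(tuple(selectors))
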