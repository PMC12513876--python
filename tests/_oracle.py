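"""Independent brute-force oracles used by the tests.

Everything here works on plain Python structures (node lists, edge tuples,
label dicts) and materializes every dyad slot explicitly with loops — no
code is shared with the package's vectorized/denominator-based paths.
"""

from itertools import combinations, permutations


def slot_list(node_ids, edges, directed, multi):
    """Materialize every completed-graph slot as (source, target, weight, observed).

    ``edges`` are (source, target, multi_index, weight) with canonical
    (sorted) node order for undirected graphs.  Unobserved dyads contribute
    a single zero-weight slot; observed dyads contribute one slot per
    (multi-)edge.
    """
    if directed:
        pairs = list(permutations(node_ids, 2))
    else:
        pairs = [tuple(sorted(p)) for p in combinations(node_ids, 2)]
    by_pair = {}
    for s, t, _, w in edges:
        by_pair.setdefault((s, t), []).append(w)
    slots = []
    for pair in pairs:
        weights = by_pair.get(pair, [])
        if weights:
            for w in weights:
                slots.append((pair[0], pair[1], w, True))
        else:
            slots.append((pair[0], pair[1], 0.0, False))
    return slots


def pattern_covers(labels, pattern):
    """pattern: dict attr -> set of admissible values."""
    return all(attr in labels and labels[attr] in values
               for attr, values in pattern.items())


def eqneq_labels(attrs_a, attrs_b):
    return {k: ("EQ" if attrs_a[k] == attrs_b[k] else "NEQ") for k in attrs_a}


def comparison_labels(attrs_src, attrs_dst, numeric):
    out = {}
    for k in attrs_src:
        a, b = attrs_src[k], attrs_dst[k]
        if k in numeric:
            out[k] = "same" if float(a) == float(b) else ("higher" if float(b) > float(a) else "lower")
        else:
            out[k] = f"({a},{b})"
    return out


def _population_variance(values):
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / n


def oracle_target(node_ids, edges, node_attrs, pattern, measure, metric,
                  directed, multi, numeric=()):
    """Normalized target t_P by explicit slot enumeration.

    Labels are recomputed here from node attributes (eqneq for undirected,
    comparison for directed).  Returns None when the measure's denominator
    is empty (no admissible dyads).
    """
    slots = slot_list(node_ids, edges, directed, multi)

    def labels_for(s, t):
        if directed:
            return comparison_labels(node_attrs[s], node_attrs[t], numeric)
        return eqneq_labels(node_attrs[s], node_attrs[t])

    covered = [(s, t, w, obs) for s, t, w, obs in slots
               if pattern_covers(labels_for(s, t), pattern)]
    if measure in ("qB", "qBD", "qBM"):
        if not covered:
            return None
        values = [w for _, _, w, _ in covered]
    else:
        observed_covered = [(s, t, w) for s, t, w, obs in covered if obs]
        nodes = set()
        for s, t, _ in observed_covered:
            nodes.update((s, t))
        if len(nodes) < 2:
            return None
        # every slot among the covered node set, with non-covered observed
        # edges zeroed out (they are outside E_P but occupy a slot)
        values = []
        for s, t, w, obs in slots:
            if s in nodes and t in nodes:
                in_ext = obs and pattern_covers(labels_for(s, t), pattern)
                if measure in ("qS", "qDS") and obs:
                    # simple measures: one slot per dyad regardless of
                    # multiplicity (the inputs are simple graphs anyway)
                    pass
                values.append(w if in_ext else 0.0)
    if metric == "mean":
        return sum(values) / len(values)
    return _population_variance(values)
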