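# compsd — compositional subgroup discovery on attributed interaction networks

`compsd` mines *dyadic* patterns in social interaction networks: given a
weighted interaction graph (who interacted with whom, for how long, how
often) and descriptive attributes of the actors, it finds conjunctive
descriptions of dyad subgroups — such as `gender=EQ AND track=EQ` — whose
interaction durations deviate most from what a randomization null model
expects. It is aimed at researchers analyzing sensor-derived social data:
RFID face-to-face contact networks, or positional (movement) recordings
from which directed "who approached whom" networks are inferred.

## The model

An *edge-attributed database* holds one record per dyad slot of the
completed graph (unobserved dyads are kept with weight 0). Dyads are
labeled compositionally from node attributes: undirected edges get
`EQ`/`NEQ` per attribute; directed edges get comparison labels
(`(F,M)`, `higher`/`lower`/`same`), or copies of the target
(*to-node*) / source (*from-node*) attributes. Node tables can be enriched
with binned network metrics (degree, betweenness, closeness, eigenvector,
hub/authority).

A pattern *P* (conjunction of selectors over dyad labels) is scored by the
z-score of its normalized dyadic mean t_P against a sampling null model.
Seven quality measures differ in the slot universe of the mean:

| measure | graph | t_P denominator |
|---------|-------|-----------------|
| q_S | undirected simple | n_P (n_P − 1)/2 over the covered node set |
| q_M | undirected multi | + Σᵢ (mᵢ − 1) multi-edge slots |
| q_DS | directed simple | n_P (n_P − 1) |
| q_DM | directed multi | + Σᵢ (mᵢ − 1) |
| q_B | undirected simple | \|E_CP\|: completed-graph slots covered by *P* |
| q_BD | directed simple | \|E_SP\|: same, directed |
| q_BM | directed multi | \|E_MP\|: same, plus observed multi-edges |

The subgraph-normalized family (q_S … q_DM) compares a pattern's edges
against *all* dyads among its covered nodes; the balanced family
(q_B/q_BD/q_BM) normalizes over only the dyads *compatible with the
pattern's semantics* — for `gender=EQ` only F–F and M–M slots — which is
the right lens for homophily questions. Significance comes from drawing
*r* equal-size slot subsets without replacement from the zero-padded
global universe; a Shapiro–Wilk gate decides between the normal-law and
the add-one empirical p-value. Signed analyses (e.g. "less liked"
nominations) multiply edge weights by a {0,1} overlay, where 0 means
"no information", before scoring.

Directed graphs are built from trajectories by an approach rule: *i*
approaches *j* at a time step when their distance is within `maxdist` and
the cosine between the displacement vector r_ij and *i*'s velocity is
positive. The simple digraph counts approach steps; the multidigraph keeps
one edge per uninterrupted approach episode.

## Worked example

Generate a synthetic 30-actor contact network with a planted
gender-homophilous duration effect, build the graph, and rank patterns with
the balanced measure q_B:

```sh
compsd simulate --kind network --n 30 --effect 135 --seed 11 \
       --nodes-out nodes.tsv --data-out contacts.tsv
compsd build --contacts contacts.tsv --edges-out edges.tsv
compsd discover --nodes nodes.tsv --edges edges.tsv \
       --measure qB --r 1000 --top-k 5 --max-depth 2 --seed 11 --out results.tsv
```

`results.tsv` then contains:

```
 rank                 pattern  n_nodes  n_edges   t_P     z       p  denominator
    1               Gender=EQ       30       74 64.77  5.79 6.8e-09          219
    2 Gender=EQ AND Track=NEQ       30       50 68.70  4.54 5.7e-06          141
    3  Gender=EQ AND Track=EQ       30       24 57.67  1.78   0.086           78
    4               Track=NEQ       30       98 47.51  1.33    0.18          279
    5                Track=EQ       30       50 37.30 -1.24    0.22          156
```

The planted pattern `Gender=EQ` ranks first: its 219 gender-equal dyad
slots average t_P = 64.8 s of contact, 5.8 null standard deviations above
what equally many random dyads of this network carry (p ≈ 7·10⁻⁹), while
the track patterns — nothing was planted on them — stay near z = 0. The
same pipeline runs end-to-end from a YAML config via `compsd run`, and on
movement data via `compsd build --trajectory ... --maxdist ...`.

As a desk check, the published summary statistics of the two conference
contact networks follow from their participant and unique-contact counts:

```sh
$ compsd summary --participants 77 --unique-contacts 1004
mean degree: 26.08
density: 0.34
```

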