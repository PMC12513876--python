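# Methods

## The dyadic model

The unit of analysis is the *dyad slot*: an ordered (digraph) or unordered
(graph) pair of actors, present in the database whether or not an
interaction was observed. Unobserved slots carry weight 0 and
multiplicity 1; observed slots carry the interaction duration (seconds for
contact data, time steps for trajectory data), and multigraph tables hold
one record per interaction episode. Completing the graph in this way is
what makes both the balanced quality measures and the sampling null model
well defined: "no interaction" is data, not missingness.

Patterns are conjunctions of selectors over dyad labels, at most one
selector per attribute, kept in canonical attribute order so equal
conjunctions compare and render identically. Extended selectors (value
sets, i.e. internal disjunctions) are representable and evaluable, but the
search enumerates atomic selectors only: subset enumeration is exponential
and atomic labels are what the intended analyses use. Records missing a
label an active selector needs are excluded from coverage by default
(`missing="exclude"`); a strict mode raises instead.

## Quality measures and their null

All seven measures score a pattern by z = (t_P − mean of null statistics) /
(their sd), where t_P is the pattern's normalized dyadic mean (or population
variance). The two families differ only in the denominator slot set:

* **subgraph-normalized** (q_S, q_M, q_DS, q_DM): the covered *observed*
  edges' weights, normalized over every possible dyad among the covered
  node set — n_P(n_P−1)/2 undirected, n_P(n_P−1) directed, plus
  Σ(mᵢ−1) extra slots for multigraphs. Observed edges among covered nodes
  that the pattern does not cover occupy zero-valued slots. The
  multiplicity sum is taken over dyads, with unobserved dyads contributing
  mᵢ = 1 (hence nothing).
* **balanced** (q_B, q_BD, q_BM): the mean over exactly the
  completed-graph slots whose labels are compatible with the pattern
  (E_CP / E_SP / E_MP). This normalizes by pattern semantics, not subgroup
  size, and is the measure of choice for homophily questions. q_BM is
  defined for the directed multigraph setting; the implementation reuses
  the same slot semantics with unordered slots for undirected multigraphs.

The variance metric replaces the mean with the population variance of the
zero-padded weight multiset over the same slot set, keeping the slot
universe identical between the two metrics.

**Null model.** The sampling universe R is the zero-padded vector of all
slot weights of the whole graph for the measure's family. For a pattern
whose target was normalized over *size* slots, the null draws r
(default 1000) uniform slot subsets of that size without replacement and
records the per-draw statistic. Using the denominator as the sample size
is the only choice that makes t_P and the sampled statistics
commensurable — both are means over equally many zero-padded slots; for
balanced measures the size is the balanced slot count |E_CP|. A
Shapiro–Wilk test at α = 0.05 gates the p-value: the normal law when it
passes, the add-one (Davison–Hinkley) empirical p otherwise, so p is never
exactly 0. The z-score is signed and reported two-sided by default; low
tails are meaningful (unexpectedly *short* interactions) and the search
tail is a flag.

Degenerate nulls are a real boundary, not an error to paper over: a
pattern whose denominator exhausts the whole universe (e.g. one that
covers every node of a small dense graph under q_S) yields constant sample
statistics; such patterns are skipped with a warning during search. The
constant case is detected by zero range, not by a floating-point-fragile
sd comparison.

**Determinism.** Every null draw seeds a fresh generator. During search
each pattern's seed is derived from the top-level seed and a CRC of the
canonical pattern text, so results do not depend on enumeration order and
rerunning a configuration is byte-identical.

## Graph construction

Face-to-face contact lists become undirected graphs: simple (durations
summed per pair) or multi (one edge per contact). Trajectories become
digraphs via the approach rule: at each step, compute the distance matrix;
for each ordered pair within `maxdist`, actor *i* approaches *j* iff the
cosine between r_ij = (x_j − x_i, y_j − y_i) and i's velocity is strictly
positive. Perpendicular motion (cosine 0), a zero velocity, or coincident
positions produce no event — a stationary actor does not approach. Both
directions may fire in the same step (mutual approach). The simple digraph
counts event steps per ordered pair; the multidigraph opens one edge per
maximal run of events over consecutive recorded time steps, weighted by
run length — a step at which either actor is unrecorded produces no event
and therefore breaks the run. Per ordered pair, episode weights sum
exactly to the simple-digraph weight. Velocities missing from a trajectory
are derived by forward differences, the last step copying the previous
one. Time steps are assumed uniformly spaced; one step is the weight unit.
`maxdist` is deliberately a mandatory parameter with no default: it is a
property of the sensor and setting, not of the method. The cosine uses
actor *i*'s own velocity, not the relative velocity of the pair.

Sign overlays are {0,1} relations with a semantics flag
(positive/negative). Weight 0 means "unknown", never "opposite tie":
absence of a nomination is not evidence of the opposite relationship.
Applying an overlay multiplies edge weights element-wise; all measures
then work unchanged on the signed graph.

## Edge labeling choices

For directed comparison labels on numeric attributes the label describes
the *target's* value relative to the source's (edge a→b with ages 0→1 is
`higher`). To-node copies the attributes of the node the edge points to,
from-node those of the origin. Equal-frequency binning cuts sorted
positions at multiples of n/k; a group of tied values takes the bin of its
first sorted position (the lower bin), which keeps binning deterministic
at the cost of uneven bins under heavy ties. Centralities on multigraphs
are computed on the weight-aggregated simple projection; closeness uses
the Wasserman–Faust component-scaled form so disconnected graphs stay
finite; eigenvector centrality failing to converge within 1000 iterations
is an error, not a silent fallback.

## Search

The candidate space — all conjunctions of ≤ `max_depth` atomic selectors
over distinct attributes — is enumerated exhaustively. With the label
alphabets that arise here (≤ 8 attributes, 2–3 values each) this is a few
hundred candidates at most, and z-score qualities admit no tight
anti-monotone bound that would justify pruning machinery; only the size
constraints (`min_observed_edges`, default 1; `min_nodes`) filter
candidates. Ties in the ranking break by (|z| desc, pattern length asc,
rendered pattern asc). Default depth is 3; the deepest interpretable
patterns in practice run four or five selectors, so depth is a
configuration floor, not a claim.

## Synthetic data

The generators produce the two input kinds with known planted structure,
at the scale of the reference settings rather than as statistical replicas
of any real data set.

* **Attributed contact networks**: n = 30 actors (a scaled-down
  conference), binary `Gender` plus a three-valued `Track`, dyads observed
  with density 0.34 (the observed contact-network density), durations
  exponential with mean 60 s — interaction durations are heavy-tailed and
  right-skewed, which the exponential captures qualitatively. The planted
  effect shifts the mean of pattern-compatible dyads additively
  (multiplicative optional). In recovery experiments the effect is
  expressed in units of the slot-universe sd
  σ = scale·√(2·density − density²) ≈ 45 s, so "3 sd" ≈ 135 s.
* **Trajectories**: agents on bounded random walks in a 40×40 arena
  (default 18 agents, 600 steps, unit step length — playground scale;
  tests use smaller sizes for speed). With probability `bias` an agent
  steps toward its nearest same-group peer, inducing directed approach
  homophily; recorded velocities are the realized post-clipping
  displacements.
* **Sign overlays**: each actor nominates a fixed number of distinct
  others (default 3, mirroring "less liked" peer-nomination designs).

What the generators do *not* emulate: sensor noise and dropout, spatial
structure of real playgrounds (obstacles, attractors), temporal
nonstationarity, or attribute correlations. Tests passing on this data
demonstrate correctness of the machinery and sensitivity under clean
planted effects, not performance under real sensor artifacts.

A statistical note on trajectory tests: approach events are strongly
autocorrelated in time (nearby agents stay nearby), so event counts must
be compared at the level of ordered pairs — pooling events and applying a
binomial standard error drastically understates the variance.

## Problem sizes and numerics

Oracle-equivalence checks run hundreds of random graphs at n ≤ 6, where a
brute-force slot-materializing oracle is exact and fast; agreement is
required to 1e−12 (pure arithmetic, no sampling). Null calibration uses a
complete 20-node homogeneous graph, subgroups of 60 slots, r = 500,
1000 trials; recovery uses 20 generator seeds at n = 30 with r = 500;
trajectory homophily uses 12 agents × 300 steps over 12 seeds. These sizes
make the full suite run in seconds while keeping every estimate's Monte
Carlo error well inside its assertion band.

## Known limitations

* q_S-family measures on small dense graphs: patterns covering all nodes
  exhaust the universe and are skipped as degenerate; the balanced family
  is the appropriate tool there.
* No optimistic-estimate pruning; search cost is linear in the candidate
  count times the null sampling cost.
* Internal disjunctions are not searched, only evaluable when constructed
  explicitly.
* The empirical p-value resolution is bounded by 1/(r+1).
* Trajectory ingestion assumes cleaned, uniformly sampled positions;
  there is no gap interpolation beyond forward-difference velocities and
  no coordinate projection.
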