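# Methods

## The pile-sort data model

A sorting study is a set of quotes, a set of sorters, and at most one pile
assignment per (sorter, quote) pair.  Pile identity is scoped to the
sorter: the label "2" used by two sorters names two unrelated piles, so a
sorter's piles are simply a partition of the quotes that sorter placed.
Two irregularities are treated as legal but flagged by the validator
rather than rejected, because transcription of physical piles cannot rule
them out:

* a sorter leaving some quotes unsorted (co-sort counts then omit those
  pairs for that sorter);
* per-sorter pile counts outside the 3–12 range typical of sorting panels.

Conflicting assignments (one sorter, one quote, two piles) are a hard
error naming the offending pair, since they make the partition semantics
undefined.  Reading is row-order invariant, and the canonical writer
sorts by sorter then quote so identical studies serialise to identical
bytes.

## The co-occurrence network

The canonical stored edge quantity is the integer co-sort count c_ij; the
inverse weight w_ij = 1/c_ij is always derived on demand, so
w_ij · c_ij = 1 holds exactly and no floating-point drift can enter the
serialisation round trip (weights are recomputed from counts on import).
Counts are also what the diagram needs, since edge thickness encodes the
number of agreeing sorters.  Quotes never co-sorted with anything remain
isolated nodes and surface as singleton groups; no edge thresholding is
applied — every pair with c_ij ≥ 1 is connected.

Two read-outs of the same edge serve different consumers:

* **similarity** mode, A_ij = c_ij: modularity and greedy merging, where
  more agreeing sorters must mean a stronger tie;
* **distance** mode, w_ij = 1/c_ij: shortest-path computations, where more
  agreeing sorters must mean a shorter path.

This split resolves the one place where the inverse-weight convention is
otherwise ambiguous: feeding inverse weights into modularity as strengths
would *invert* the clustering objective, while feeding them into shortest
paths as lengths is exactly what makes bridges between themes carry high
betweenness.  The toolkit fixes this reading once, in the network module,
rather than per call site.

## Community detection

Both algorithms optimise Newman–Girvan modularity with similarity-mode
strengths and never take the number of groups as an input.

**Girvan–Newman (divisive).**  Exact edge betweenness is recomputed on
the full remaining graph after every removal — no incremental
approximation — which is affordable at pile-sort scale (tens of quotes,
at most a few thousand edges).  The betweenness primitive itself is
evaluated by igraph's exact weighted algorithm for speed; unit tests pin
it against networkx's implementation.  A history level is recorded each
time a removal increases the number of connected components, from the
initial component structure down to all singletons.

**Greedy modularity (agglomerative).**  The CNM update is used with exact
bookkeeping of community strengths: merging communities a and b changes Q
by ΔQ = 2(e_ab − a_a a_b), where e_ab is the fraction of total strength
between them and a_x the fraction of strength ends in x.  All community
pairs are candidates; disconnected pairs have negative gain, so they are
only merged after every within-component gain is exhausted, which lets
the history reach a single group even on disconnected networks.  Each
level's Q is recomputed directly from the partition rather than
accumulated, so recorded values carry no incremental rounding.

**Determinism.**  Ties in betweenness or ΔQ are broken toward the
lexicographically smallest node-id (or community-label) pair.  With no
randomness anywhere in detection, repeated runs are bit-identical;
relabelling nodes permutes results without changing the grouping.

**Selection.**  `best_partition` takes the maximum-Q level, breaking
exact ties toward fewer groups (a coarser description of the same score
is easier for a panel to discuss), then toward the earlier level.
`select_final` keeps whichever algorithm's history attains the higher
maximum Q — Q is the objective both pursue, so it is the natural arbiter —
and always attaches the cross-algorithm ARI/NMI and contingency table.
Equal Q with the same grouping is reported as "consensus"; equal Q with
different groupings falls back to alphabetical algorithm order.

**Oracle.**  `brute_force_best_partition` enumerates every set partition
(Bell-number search, capped at 10 nodes) and is used purely as a test
oracle; greedy agglomeration can be verified never to exceed it and to
match it on most small random instances and on all disjoint-clique
instances.

## Isolated nodes and degenerate inputs

Modularity is undefined on an edgeless network (m = 0) and raises; both
algorithms special-case that network to a single-level all-singletons
history with Q recorded as 0 by convention.  Isolated nodes are excluded
from greedy agglomeration (their ΔQ is identically 0, which would
otherwise tie with meaningful merges) and re-attached as singleton groups
at every level; in the divisive algorithm they are their own components
from the start.  Q of the single-group partition is identically 0 by the
algebra of the formula, which the tests assert to 1e-12.

## Agreement indices

The adjusted Rand index (Hubert–Arabie, pair-counting with chance
correction) and normalised mutual information (arithmetic-mean
normalisation) are computed from the group-by-group contingency table.
Degenerate cases follow the conventions of the widely used scikit-learn
implementations (which the tests use as an independent check): two
identical trivial partitions score 1, a zero denominator otherwise scores
0.

## The planted-theme generator

The generator emulates the structure of a real panel study — default
N = 49 quotes, S = 9 sorters, K = 6 latent themes, quotes assigned to
themes round-robin — with three sorter-level corruption mechanisms:

* **merge** (p_merge, default 0.2): each adjacent theme pair is lumped
  into one pile, independently per sorter; adjacency means consecutive
  theme indices, avoiding a random-graph merge model;
* **split** (p_split, default 0.2): each unmerged theme is divided into
  two piles, members assigned to a half uniformly;
* **noise** (ε, default 0.1): each (sorter, quote) independently lands in
  a uniformly random pile of that sorter instead of its home pile.

With merge and split at their defaults, per-sorter pile counts
concentrate in the 3–12 range panels actually produce.  At ε = 0 with
merging and splitting off, every sorter reproduces the planted partition,
the network is K disjoint uniform cliques, and both algorithms provably
recover the themes.  Misassignment draws uniformly over *all* of the
sorter's piles so that ε = 1 is the exact no-signal null: every quote's
pile is iid uniform, within-theme and cross-theme co-sort rates are
equidistributed, and recovery ARI is centred on 0.  (Excluding the home
pile from the draw would leave a residual within-theme excess of order
1/K at full noise and no clean null.)

Seeding uses one root seed with an independent per-sorter substream keyed
by (seed, sorter index), so adding a sorter never perturbs existing
sorters' piles; replicate r of a recovery experiment uses root seed
seed + r.

What the generator does **not** model: quote-difficulty heterogeneity
(every quote is equally confusable), sorter-specific noise rates,
correlated errors between similar quotes, partial sorting, and themes of
deliberately unequal size.  Passing recovery tests therefore show that
the pipeline recovers clean-to-moderately-noisy block structure, not that
it resolves the subtler disagreement patterns of real panels.

## Diagram and report conventions

Node colour encodes group membership using a six-colour palette (light
blue, green, pink, red, yellow, orange) applied to groups ordered by size
(descending) then label — a reproducible colouring that does not depend
on arbitrary group indices; with more groups than colours the palette
cycles with a warning.  Edge display width is proportional to c_ij,
capped at 8× the base width so dense high-agreement diagrams stay
legible.  Layout is a seeded force-directed embedding with attraction
proportional to c_ij (equivalently, inverse weights as target lengths),
so strongly co-sorted quotes are drawn close; coordinates are exported as
JSON for external editing.  The group report lists quotes verbatim, one
section per group, in (group label, quote id) order, carries no
timestamps, and appends the edit log when panel reassignments exist —
regeneration on the same inputs is byte-identical.

## Manual reassignment

Panels routinely move quotes between algorithmic groups during
interpretation.  `reassign` models this as append-only provenance: the
grouping stores the untouched algorithmic base partition plus an ordered
edit log, and the current partition is always derived by replaying the
log.  No-op moves are recorded too, since "the panel confirmed this
placement" is itself provenance.

## Problem sizes used in validation

The validation suite and the acceptance script run at the scale the
method is designed for: exhaustive-search comparisons on 50 random
networks of up to 8 nodes; closed-form modularity checks on 100 random
networks; recovery experiments with 30 replicates per noise level at
49 quotes × 9 sorters × 6 themes; and a full 49 × 9 pipeline run
(network, both detections, diagram, report), which completes in a few
seconds on one CPU.

## Known limitations

* Girvan–Newman recomputes betweenness over the whole remaining graph
  per removal; beyond a few hundred quotes this becomes the bottleneck.
* The reconciliation rule compares only two algorithms; no multi-method
  consensus matrix is built.
* Modularity's resolution limit applies: very small true themes attached
  to much larger ones may not be separated at the maximum-Q level.
* The generator's noise model is exchangeable across quotes and sorters;
  none of the heterogeneity of real panels is fitted or modelled.
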