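"""Community detection on the quote co-occurrence network.

Two independently implemented, fully deterministic algorithms partition the
network into groups with dense internal and sparse external connections —
the groupings that seed the panel's theme discussion:

* :func:`girvan_newman` — divisive: repeatedly remove the edge with the
  highest betweenness (shortest paths measured with the inverse-count
  weights ``w_ij = 1/c_ij`` as lengths, so strongly co-sorted quotes are
  close and bridges between themes carry many shortest paths);
* :func:`greedy_modularity` — agglomerative: start from singletons and
  repeatedly apply the merge with the largest modularity gain.

Both score candidate partitions with Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j)

where the edge strength is the co-sort count, ``A_ij = c_ij`` ("similarity"
mode), ``k_i = sum_j A_ij`` and ``m = (1/2) sum_ij A_ij``.  The number of
groups is never fixed in advance: it emerges from the maximum-Q level of
each algorithm's merge history.

Ties (equal betweenness, equal modularity gain) are broken toward the
lexicographically smallest node-id pair, making both algorithms
bit-reproducible without randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

import igraph as ig
import networkx as nx

from .cooccurrence import CooccurrenceNetwork
from .errors import ValidationError
from .partitions import Partition

__all__ = [
    "MergeHistory",
    "modularity",
    "girvan_newman",
    "greedy_modularity",
    "best_partition",
    "brute_force_best_partition",
]


# ---------------------------------------------------------------------------
# Modularity


def _strength_graph(net: CooccurrenceNetwork, weight_mode: str) -> nx.Graph:
    if weight_mode == "similarity":
        return net.similarity_graph()
    if weight_mode == "unweighted":
        g = net.similarity_graph()
        for _, _, data in g.edges(data=True):
            data["weight"] = 1
        return g
    raise ValidationError(
        f"unknown weight_mode {weight_mode!r}; use 'similarity' or 'unweighted'"
    )


def modularity(
    net: CooccurrenceNetwork, p: Partition, weight_mode: str = "similarity"
) -> float:
    """Newman-Girvan modularity Q of a partition of the network's nodes.

    ``weight_mode='similarity'`` uses edge strengths ``A_ij = c_ij``;
    ``'unweighted'`` uses ``A_ij = 1``.  Q is 0 for the single-group
    partition of any network, positive when within-group strength exceeds
    the degree-preserving random expectation, and always lies in [-1, 1].
    """
    if p.items != frozenset(net.nodes):
        raise ValidationError("partition must cover exactly the network's nodes")
    if net.n_edges == 0:
        raise ValidationError("modularity is undefined on an edgeless network (m = 0)")
    g = _strength_graph(net, weight_mode)
    m = g.size(weight="weight")
    degree = dict(g.degree(weight="weight"))
    internal: dict = {}
    for u, v, data in g.edges(data=True):
        if p[u] == p[v]:
            internal[p[u]] = internal.get(p[u], 0.0) + data["weight"]
    q = 0.0
    for label, members in p.groups.items():
        d = sum(degree[n] for n in members)
        q += internal.get(label, 0.0) / m - (d / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Merge histories


@dataclass(frozen=True)
class MergeHistory:
    """Ordered sequence of nested partitions with the modularity of each.

    ``direction`` is "divisive" (coarse to fine) or "agglomerative" (fine to
    coarse); consecutive levels are nested.  Only the final published
    grouping matters to end users, but the full history makes the selection
    auditable.
    """

    levels: tuple[tuple[Partition, float], ...]
    algorithm: str
    direction: str

    @property
    def max_q(self) -> float:
        return max(q for _, q in self.levels)

    def to_json(self, dest: Union[str, Path, IO[str]]) -> None:
        payload = {
            "algorithm": self.algorithm,
            "direction": self.direction,
            "levels": [
                {
                    "n_groups": part.n_groups,
                    "q": q,
                    "assignment": {k: str(v) for k, v in sorted(part.assignment.items())},
                }
                for part, q in self.levels
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text, encoding="utf-8")


def best_partition(h: MergeHistory) -> Partition:
    """The history level with maximal Q.

    Exact ties are broken toward fewer groups, then toward the earlier
    level, so the choice is deterministic.
    """
    if not h.levels:
        raise ValidationError("empty merge history")
    best = None
    best_key = None
    for part, q in h.levels:
        key = (q, -part.n_groups)
        if best_key is None or key > best_key:
            best, best_key = part, key
    return best


# ---------------------------------------------------------------------------
# Girvan-Newman (divisive, edge betweenness)


def _edge_betweenness(g: nx.Graph) -> dict[tuple[str, str], float]:
    """Exact weighted edge betweenness (edge 'weight' read as length)."""
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted(tuple(sorted((u, v))) for u, v in g.edges)
    lengths = [g[u][v]["weight"] for u, v in edges]
    graph = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in edges])
    bw = graph.edge_betweenness(directed=False, weights=lengths)
    return dict(zip(edges, bw))


def _components_partition(g: nx.Graph) -> Partition:
    return Partition.from_groups(nx.connected_components(g))


def girvan_newman(net: CooccurrenceNetwork) -> MergeHistory:
    """Divisive clustering by repeated removal of the max-betweenness edge.

    Shortest paths use the inverse-count weights as lengths; each time an
    edge removal splits a component, the new component partition and its
    modularity (similarity mode) are recorded.  The history runs from the
    initial component structure down to all-singletons.  Betweenness is
    recomputed exactly after every removal; at pile-sort scale (tens of
    quotes) this is cheap.
    """
    if net.n_edges == 0:
        singletons = Partition({n: n for n in net.nodes})
        return MergeHistory(((singletons, 0.0),), "girvan_newman", "divisive")
    g = net.distance_graph()
    part = _components_partition(g)
    levels = [(part, modularity(net, part))]
    while g.number_of_edges() > 0:
        bw = _edge_betweenness(g)
        target, best = None, None
        for edge in sorted(bw):  # lexicographic tie-break: first max wins
            if best is None or bw[edge] > best:
                target, best = edge, bw[edge]
        g.remove_edge(*target)
        part = _components_partition(g)
        if part.n_groups > levels[-1][0].n_groups:
            levels.append((part, modularity(net, part)))
    return MergeHistory(tuple(levels), "girvan_newman", "divisive")


# ---------------------------------------------------------------------------
# Greedy agglomerative modularity maximisation


def greedy_modularity(net: CooccurrenceNetwork) -> MergeHistory:
    """Agglomerative clustering by greedy modularity gain (CNM scheme).

    Starts from singleton groups and repeatedly merges the pair of groups
    with the largest gain ``dQ = 2 (e_ab - a_a a_b)``, recording every level
    until one group remains.  All pairs of groups are candidates; merging
    disconnected groups has negative gain, so such merges only occur after
    every within-component gain is exhausted, and the history still reaches
    a single group on disconnected networks.  Isolated nodes take no part
    in the agglomeration and appear as singleton groups at every level.
    """
    if net.n_edges == 0:
        singletons = Partition({n: n for n in net.nodes})
        return MergeHistory(((singletons, 0.0),), "greedy_modularity", "agglomerative")

    g = net.similarity_graph()
    isolated = sorted(n for n in g.nodes if g.degree(n) == 0)
    active = sorted(n for n in g.nodes if g.degree(n) > 0)
    two_m = 2.0 * g.size(weight="weight")

    # community state; labels are the lexicographically smallest member
    members: dict[str, set[str]] = {n: {n} for n in active}
    a: dict[str, float] = {n: g.degree(n, weight="weight") / two_m for n in active}
    # e[x][y] = fraction of total strength between communities x and y
    e: dict[str, dict[str, float]] = {n: {} for n in active}
    for u, v, data in g.edges(data=True):
        w = data["weight"] / two_m
        e[u][v] = e[u].get(v, 0.0) + w
        e[v][u] = e[v].get(u, 0.0) + w

    def snapshot() -> Partition:
        groups = [sorted(ms) for ms in members.values()]
        groups += [[n] for n in isolated]
        return Partition.from_groups(groups)

    part = snapshot()
    levels = [(part, modularity(net, part))]

    while len(members) > 1:
        labels = sorted(members)
        best_pair, best_dq = None, None
        for idx, x in enumerate(labels):
            ex = e[x]
            for y in labels[idx + 1:]:
                dq = 2.0 * (ex.get(y, 0.0) - a[x] * a[y])
                if best_dq is None or dq > best_dq:
                    best_pair, best_dq = (x, y), dq
        x, y = best_pair  # x < y; merged community keeps label x
        members[x] |= members.pop(y)
        a[x] += a.pop(y)
        for z, w in e.pop(y).items():
            if z == x:
                continue
            e[z].pop(y, None)
            e[x][z] = e[x].get(z, 0.0) + w
            e[z][x] = e[z].get(x, 0.0) + w
        e[x].pop(y, None)
        part = snapshot()
        levels.append((part, modularity(net, part)))

    return MergeHistory(tuple(levels), "greedy_modularity", "agglomerative")


# ---------------------------------------------------------------------------
# Exhaustive oracle


def _set_partitions(items: list[str]):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_best_partition(
    net: CooccurrenceNetwork, max_nodes: int = 10
) -> Partition:
    """Globally maximum-modularity partition by exhaustive enumeration.

    Intended as a test oracle on tiny networks: the search visits every set
    partition (Bell-number many), so ``max_nodes`` guards against blow-up.
    Ties go to the partition with fewer groups, then lexicographic group
    order.
    """
    nodes = net.nodes
    if len(nodes) > max_nodes:
        raise ValidationError(
            f"{len(nodes)} nodes exceeds the brute-force limit of {max_nodes}"
        )
    best, best_key = None, None
    for groups in _set_partitions(nodes):
        part = Partition.from_groups(groups)
        q = modularity(net, part)
        key = (q, -part.n_groups, tuple(sorted(map(str, part.groups))))
        if best_key is None or key > best_key:
            best, best_key = part, key
    return best
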