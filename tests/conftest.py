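"""Shared fixtures: tiny hand-built studies and networks with known structure."""

import networkx as nx
import numpy as np
import pytest

from ptekit import CooccurrenceNetwork, SortRecord, SortingStudy


def make_network(edges, n_sorters=1, extra_nodes=()):
    """Network from (u, v, count) triples."""
    g = nx.Graph()
    for u, v, c in edges:
        g.add_edge(u, v, count=c)
    g.add_nodes_from(extra_nodes)
    return CooccurrenceNetwork(g, n_sorters=n_sorters)


def triangle_edges(members, count=1):
    a, b, c = members
    return [(a, b, count), (a, c, count), (b, c, count)]


@pytest.fixture
def tiny_study():
    """One sorter, three quotes, two piles: {q1, q2 | q3}."""
    return SortingStudy(
        [
            SortRecord("s1", "q1", "A"),
            SortRecord("s1", "q2", "A"),
            SortRecord("s1", "q3", "B"),
        ]
    )


@pytest.fixture
def two_triangles():
    """Two disjoint unweighted triangles; optimum is the two-triangle split."""
    return make_network(triangle_edges("abc") + triangle_edges("def"))


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by the bridge edge c-d."""
    return make_network(triangle_edges("abc") + triangle_edges("def") + [("c", "d", 1)])


def random_network(rng, max_nodes=8, n_sorters=5, p_edge=0.45):
    """Seeded random co-occurrence network with at least one edge."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j], count=int(rng.integers(1, n_sorters + 1)))
    if g.number_of_edges() == 0:
        g.add_edge(nodes[0], nodes[1], count=1)
    return CooccurrenceNetwork(g, n_sorters=n_sorters)


def random_study(rng, max_quotes=6, max_sorters=4):
    """Seeded random pile-sort study (complete sorting, random piles)."""
    n = int(rng.integers(2, max_quotes + 1))
    s = int(rng.integers(1, max_sorters + 1))
    quotes = [f"q{i}" for i in range(n)]
    records = []
    for si in range(s):
        n_piles = int(rng.integers(1, n + 1))
        for q in quotes:
            records.append(
                SortRecord(f"s{si}", q, f"p{int(rng.integers(n_piles))}")
            )
    return SortingStudy(records)


def clique_network(sizes, count=3):
    """Disjoint uniform cliques of the given sizes."""
    g = nx.Graph()
    for ci, size in enumerate(sizes):
        members = [f"c{ci}_{i}" for i in range(size)]
        g.add_nodes_from(members)
        for i in range(size):
            for j in range(i + 1, size):
                g.add_edge(members[i], members[j], count=count)
    return CooccurrenceNetwork(g, n_sorters=count)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
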