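"""Modularity, the two detection algorithms, and the exhaustive oracle."""

import networkx as nx
import pytest

from conftest import clique_network, make_network, random_network
from ptekit import (
    MergeHistory,
    Partition,
    ValidationError,
    best_partition,
    brute_force_best_partition,
    girvan_newman,
    greedy_modularity,
    modularity,
)
from ptekit.community import _edge_betweenness


def single_group(net):
    return Partition({n: "all" for n in net.nodes})


class TestModularity:
    def test_single_group_is_zero(self, rng):
        for _ in range(20):
            net = random_network(rng)
            assert abs(modularity(net, single_group(net))) < 1e-12

    def test_two_disjoint_triangles(self, two_triangles):
        p = Partition.from_groups([set("abc"), set("def")])
        assert modularity(two_triangles, p, "unweighted") == pytest.approx(0.5)

    def test_split_single_edge(self):
        net = make_network([("a", "b", 1)])
        p = Partition({"a": "x", "b": "y"})
        assert modularity(net, p, "unweighted") == pytest.approx(-0.5)

    def test_partition_must_cover_nodes(self, two_triangles):
        with pytest.raises(ValidationError):
            modularity(two_triangles, Partition({"a": "x"}))

    def test_edgeless_network_undefined(self):
        net = make_network([], extra_nodes=["a", "b"])
        with pytest.raises(ValidationError):
            modularity(net, Partition({"a": "x", "b": "y"}))

    def test_unknown_weight_mode(self, two_triangles):
        with pytest.raises(ValidationError):
            modularity(two_triangles, single_group(two_triangles), "distance")

    def test_agrees_with_networkx(self, rng):
        # independent oracle: networkx's modularity on the similarity graph
        for _ in range(20):
            net = random_network(rng)
            g = net.similarity_graph()
            part = best_partition(greedy_modularity(net))
            ours = modularity(net, part)
            theirs = nx.community.modularity(
                g, part.groups.values(), weight="weight"
            )
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestEdgeBetweenness:
    def test_matches_networkx(self, rng):
        for _ in range(10):
            net = random_network(rng)
            g = net.distance_graph()
            ours = _edge_betweenness(g)
            theirs = nx.edge_betweenness_centrality(
                g, weight="weight", normalized=False
            )
            for (u, v), val in theirs.items():
                assert ours[tuple(sorted((u, v)))] == pytest.approx(val)


class TestGirvanNewman:
    def test_bridge_removed_first(self, bridged_triangles):
        h = girvan_newman(bridged_triangles)
        # the first split must be the two triangles
        two_group = next(p for p, _ in h.levels if p.n_groups == 2)
        assert two_group.as_group_sets() == frozenset(
            [frozenset("abc"), frozenset("def")]
        )
        _, q = next((p, q) for p, q in h.levels if p.n_groups == 2)
        assert q == pytest.approx(5 / 14)

    def test_history_spans_one_component_to_singletons(self, bridged_triangles):
        h = girvan_newman(bridged_triangles)
        assert h.levels[0][0].n_groups == 1
        assert h.levels[-1][0].n_groups == 6
        counts = [p.n_groups for p, _ in h.levels]
        assert counts == sorted(counts)

    def test_edgeless_network_gives_singletons_only(self):
        net = make_network([], extra_nodes=list("abc"))
        h = girvan_newman(net)
        assert len(h.levels) == 1
        assert h.levels[0][0].n_groups == 3

    def test_uniform_counts_match_unit_counts(self, rng):
        # constant distance weights cannot change the removal order
        for _ in range(5):
            net1 = random_network(rng, n_sorters=1)  # all counts 1
            edges3 = [(u, v, 3) for u, v, _ in net1.edges()]
            net3 = make_network(edges3, n_sorters=3, extra_nodes=net1.nodes)
            h1, h3 = girvan_newman(net1), girvan_newman(net3)
            assert [p.as_group_sets() for p, _ in h1.levels] == [
                p.as_group_sets() for p, _ in h3.levels
            ]

    def test_relabelling_only_permutes_the_result(self, bridged_triangles):
        mapping = {"a": "z9", "b": "z8", "c": "z7", "d": "z6", "e": "z5", "f": "z4"}
        edges = [(mapping[u], mapping[v], c) for u, v, c in bridged_triangles.edges()]
        relabelled = make_network(edges)
        b1 = best_partition(girvan_newman(bridged_triangles))
        b2 = best_partition(girvan_newman(relabelled))
        mapped = frozenset(
            frozenset(mapping[m] for m in g) for g in b1.as_group_sets()
        )
        assert mapped == b2.as_group_sets()


class TestGreedyModularity:
    def test_two_triangles_best_level(self, two_triangles):
        best = best_partition(greedy_modularity(two_triangles))
        assert best.as_group_sets() == frozenset([frozenset("abc"), frozenset("def")])
        assert modularity(two_triangles, best) == pytest.approx(0.5)

    def test_single_edge_levels(self):
        net = make_network([("a", "b", 1)])
        h = greedy_modularity(net)
        qs = [q for _, q in h.levels]
        assert qs == pytest.approx([-0.5, 0.0])
        assert best_partition(h).n_groups == 1

    def test_levels_are_nested_coarsenings(self, rng):
        for _ in range(5):
            net = random_network(rng)
            h = greedy_modularity(net)
            for (p1, _), (p2, _) in zip(h.levels, h.levels[1:]):
                assert p2.n_groups == p1.n_groups - 1
                fine = p1.as_group_sets()
                for coarse_group in p2.as_group_sets():
                    parts = [g for g in fine if g <= coarse_group]
                    assert frozenset().union(*parts) == coarse_group

    def test_isolated_nodes_stay_singletons(self):
        net = make_network([("a", "b", 2), ("b", "c", 2)], n_sorters=2,
                           extra_nodes=["lonely"])
        best = best_partition(greedy_modularity(net))
        assert best["lonely"] == "lonely"
        assert frozenset(["lonely"]) in best.as_group_sets()

    def test_relabelling_only_permutes_the_result(self, two_triangles):
        mapping = dict(zip("abcdef", ["p", "q", "r", "x", "y", "z"]))
        edges = [(mapping[u], mapping[v], c) for u, v, c in two_triangles.edges()]
        best1 = best_partition(greedy_modularity(two_triangles))
        best2 = best_partition(greedy_modularity(make_network(edges)))
        mapped = frozenset(
            frozenset(mapping[m] for m in g) for g in best1.as_group_sets()
        )
        assert mapped == best2.as_group_sets()


class TestBestPartition:
    def _history(self, qs):
        levels = tuple(
            (Partition({f"n{i}": f"g{i % (len(qs) - k)}" for i in range(4)}), q)
            for k, q in enumerate(qs)
        )
        return MergeHistory(levels, "fake", "agglomerative")

    def test_max_q_level_selected(self):
        h = self._history([-0.1, 0.4, 0.3])
        assert best_partition(h) is h.levels[1][0]

    def test_all_equal_q_prefers_coarsest(self):
        h = self._history([0.2, 0.2, 0.2])
        # later levels have fewer groups in this fake agglomerative history
        assert best_partition(h) is h.levels[2][0]

    def test_empty_history_rejected(self):
        with pytest.raises(ValidationError):
            best_partition(MergeHistory((), "fake", "divisive"))


class TestBruteForce:
    def test_two_triangles_optimum(self, two_triangles):
        best = brute_force_best_partition(two_triangles)
        assert best.as_group_sets() == frozenset([frozenset("abc"), frozenset("def")])

    def test_complete_uniform_graph_is_one_group(self):
        nodes = list("abcd")
        edges = [(u, v, 2) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        net = make_network(edges, n_sorters=2)
        assert brute_force_best_partition(net).n_groups == 1

    def test_two_node_network_merges(self):
        net = make_network([("a", "b", 1)])
        assert brute_force_best_partition(net).n_groups == 1

    def test_node_limit_guard(self, rng):
        net = random_network(rng, max_nodes=8)
        with pytest.raises(ValidationError):
            brute_force_best_partition(net, max_nodes=2)

    def test_greedy_never_beats_exhaustive_search(self, rng):
        exact = 0
        total = 50
        for _ in range(total):
            net = random_network(rng)
            q_opt = modularity(net, brute_force_best_partition(net))
            q_greedy = modularity(net, best_partition(greedy_modularity(net)))
            assert q_greedy <= q_opt + 1e-9
            if q_greedy == pytest.approx(q_opt, abs=1e-9):
                exact += 1
        assert exact / total >= 0.8

    def test_both_algorithms_exact_on_disjoint_cliques(self):
        for sizes in [(3, 3), (3, 4), (2, 3, 3), (4, 4)]:
            net = clique_network(sizes)
            q_opt = modularity(net, brute_force_best_partition(net))
            for algorithm in (girvan_newman, greedy_modularity):
                q = modularity(net, best_partition(algorithm(net)))
                assert q == pytest.approx(q_opt, abs=1e-12)
                # and components are never merged across at the best level
                best = best_partition(algorithm(net))
                for group in best.as_group_sets():
                    prefixes = {m.split("_")[0] for m in group}
                    assert len(prefixes) == 1
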