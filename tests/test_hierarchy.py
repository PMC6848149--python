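import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

import oracles
from hiernet import hierarchy, synthdata


def nmi(true_labels, found_labels, nodes):
    return normalized_mutual_info_score(
        [true_labels[n] for n in nodes], [found_labels[n] for n in nodes]
    )


class TestModularity:
    def test_two_disjoint_triangles(self, two_k3):
        labels = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}
        assert hierarchy.modularity(two_k3, labels) == pytest.approx(0.5)

    def test_single_community_zero(self, kite):
        labels = dict.fromkeys(kite.nodes, 0)
        assert hierarchy.modularity(kite, labels) == pytest.approx(0.0, abs=1e-12)

    def test_random_labels_on_complete_graph_nonpositive(self):
        K = nx.complete_graph(10)
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = {n: int(rng.integers(3)) for n in K}
            assert hierarchy.modularity(K, labels) <= 1e-12

    def test_unlabeled_node_raises(self, kite):
        with pytest.raises(ValueError, match="unlabeled"):
            hierarchy.modularity(kite, {"a": 0})


class TestLouvain:
    def test_two_cliques_split(self, two_k5_bridge):
        for seed in (0, 1, 7):
            part = hierarchy.louvain(two_k5_bridge, seed=seed)
            comms = part.communities()
            assert len(comms) == 2
            assert {frozenset(c) for c in comms} == {
                frozenset(f"a{i}" for i in range(5)),
                frozenset(f"b{i}" for i in range(5)),
            }

    def test_clique_bipartition_is_q_optimal(self, two_k5_bridge):
        # exhaustive: the clique split beats every other 2-partition
        import itertools

        nodes = sorted(two_k5_bridge.nodes)
        best_q, best_split = -1.0, None
        for assignment in itertools.product([0, 1], repeat=len(nodes) - 1):
            labels = {nodes[0]: 0}
            labels.update(dict(zip(nodes[1:], assignment)))
            if len(set(labels.values())) < 2:
                continue
            q = hierarchy.modularity(two_k5_bridge, labels)
            if q > best_q:
                best_q, best_split = q, labels
        groups = {frozenset(n for n in nodes if best_split[n] == g) for g in (0, 1)}
        assert groups == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }
        assert hierarchy.louvain(two_k5_bridge, seed=0).q == pytest.approx(best_q)

    def test_triangle_single_community(self):
        tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert len(hierarchy.louvain(tri, seed=3).communities()) == 1

    def test_determinism(self, two_k5_bridge):
        a = hierarchy.louvain(two_k5_bridge, seed=11)
        b = hierarchy.louvain(two_k5_bridge, seed=11)
        assert a.labels == b.labels and a.q == b.q

    def test_q_matches_modularity(self, two_k5_bridge):
        part = hierarchy.louvain(two_k5_bridge, seed=2)
        assert part.q == pytest.approx(
            hierarchy.modularity(two_k5_bridge, part.labels), abs=1e-12
        )


class TestTriangles:
    def test_path_k4_k5_minus_edge(self):
        assert hierarchy.count_triangles(nx.path_graph(6)) == 0
        assert hierarchy.count_triangles(nx.complete_graph(4)) == 4
        K5m = nx.complete_graph(5)
        K5m.remove_edge(0, 1)
        assert hierarchy.count_triangles(K5m) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        G = nx.gnp_random_graph(25, 0.2, seed=seed)
        assert hierarchy.count_triangles(G) == oracles.triangles_oracle(G)

    def test_qualifies(self, star5):
        assert not hierarchy.qualifies(star5)
        assert hierarchy.qualifies(nx.complete_graph(3))
        assert not hierarchy.qualifies(nx.cycle_graph(4))


class TestBuildHierarchy:
    def test_nested_cliques_recovery(self):
        G, gt = synthdata.nested_cliques(3, 2, 5, seed=0)
        tree = hierarchy.build_hierarchy(G, seed=1)
        assert tree.max_depth >= 2
        level1 = tree.communities_at(1)
        found = {n: i for i, c in enumerate(level1) for n in c.nodes}
        assert nmi(gt.labels[1], found, sorted(G.nodes)) >= 0.9

    def test_single_triangle_depth_one(self):
        tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        tree = hierarchy.build_hierarchy(tri, seed=0)
        assert tree.max_depth == 1
        (leaf,) = tree.communities_at(1)
        assert leaf.is_leaf and leaf.qualifies

    def test_triangle_free_tree_depth_one_no_qualify(self):
        T = nx.balanced_tree(2, 3)
        tree = hierarchy.build_hierarchy(T, seed=0)
        assert tree.max_depth == 1
        assert all(not c.qualifies for c in tree.communities_at(1))

    def test_partition_refinement_invariant(self):
        G, _ = synthdata.nested_cliques(3, 2, 5, seed=3)
        tree = hierarchy.build_hierarchy(G, seed=0)
        for comm in tree.walk():
            if comm.children:
                union = set().union(*(c.nodes for c in comm.children))
                assert union == set(comm.nodes)
                sizes = sum(len(c.nodes) for c in comm.children)
                assert sizes == len(comm.nodes)  # disjoint tiling

    def test_determinism_same_seed_same_tree(self):
        G, _ = synthdata.nested_cliques(3, 2, 5, seed=5)
        t1 = hierarchy.build_hierarchy(G, seed=9)
        t2 = hierarchy.build_hierarchy(G, seed=9)
        assert t1.to_json() == t2.to_json()


class TestLevelSummary:
    def test_depth_one_single_row(self):
        tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        tree = hierarchy.build_hierarchy(tri, seed=0)
        assert len(hierarchy.level_summary(tree)) == 1

    def test_nested_counts_and_q_trend(self):
        G, _ = synthdata.nested_cliques(3, 2, 5, seed=0)
        tree = hierarchy.build_hierarchy(G, seed=1)
        summary = hierarchy.level_summary(tree)
        assert summary.loc[1, "n_communities"] == 3
        qs = summary["mean_Q"].dropna().tolist()
        assert all(a > b for a, b in zip(qs, qs[1:]))  # strictly decreasing

    def test_deepest_reach_counts(self):
        G, _ = synthdata.nested_cliques(3, 2, 5, seed=0)
        tree = hierarchy.build_hierarchy(G, seed=1)
        summary = hierarchy.level_summary(tree)
        deepest = tree.max_depth
        assert summary.loc[deepest, "n_reaching_deepest"] == summary.loc[
            deepest, "n_communities"
        ]
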