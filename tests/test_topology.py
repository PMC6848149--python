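import math

import networkx as nx
import numpy as np
import pytest

import oracles
from hiernet import topology


class TestDegreeAndDistribution:
    def test_path_k4_star(self, path3, k4, star5):
        assert topology.degree(path3) == {"a": 1, "b": 2, "c": 1}
        assert set(topology.degree(k4).values()) == {3}
        assert topology.degree(star5)["c"] == 4

    def test_distribution_path(self, path3):
        assert topology.degree_distribution(path3) == {1: 2 / 3, 2: 1 / 3}

    def test_distribution_k4(self, k4):
        assert topology.degree_distribution(k4) == {3: 1.0}

    def test_distribution_hand_enumerated(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "b")])
        # degrees: a=1, c=2, d=2, b=3
        assert topology.degree_distribution(G) == {1: 1 / 4, 2: 2 / 4, 3: 1 / 4}

    def test_handshake(self):
        G = nx.gnp_random_graph(30, 0.2, seed=1)
        assert sum(topology.degree(G).values()) == 2 * G.number_of_edges()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            topology.degree_distribution(nx.Graph())


class TestClustering:
    def test_triangle_all_one(self):
        tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert all(v == 1.0 for v in topology.clustering(tri).values())

    def test_path_center_zero(self, path3):
        assert topology.clustering(path3)["b"] == 0.0

    def test_kite(self, kite):
        # c has neighbours {a, b, d}; one edge (a-b) among them
        assert topology.clustering(kite)["c"] == pytest.approx(1 / 3)


class TestNeighbourhoodConnectivity:
    def test_star(self, star5):
        cn = topology.neighbourhood_connectivity(star5)
        assert cn["c"] == 1.0
        assert all(cn[f"l{i}"] == 4.0 for i in range(4))

    def test_k4(self, k4):
        assert all(v == 3.0 for v in topology.neighbourhood_connectivity(k4).values())

    def test_path4(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        assert topology.neighbourhood_connectivity(G)["b"] == pytest.approx(1.5)

    def test_isolate_nan(self):
        G = nx.Graph([("a", "b")])
        G.add_node("iso")
        assert math.isnan(topology.neighbourhood_connectivity(G)["iso"])


class TestCloseness:
    def test_path3_scaled(self, path3):
        cc = topology.closeness(path3, convention="scaled")
        assert cc["b"] == pytest.approx(1.5)
        assert cc["a"] == pytest.approx(1.0)

    def test_complete_standard(self):
        K = nx.complete_graph(6)
        cc = topology.closeness(K, convention="standard")
        assert all(v == pytest.approx(1.0) for v in cc.values())

    def test_disconnected_raises(self, two_k3):
        with pytest.raises(ValueError, match="curate"):
            topology.closeness(two_k3)

    @pytest.mark.parametrize("seed", range(5))
    def test_conventions_same_ranking(self, seed):
        rng = np.random.default_rng(seed)
        G = oracles.random_connected_graph(rng)
        scaled = topology.closeness(G, "scaled")
        std = topology.closeness(G, "standard")
        order = lambda d: sorted(d, key=lambda n: (d[n], n))
        assert order(scaled) == order(std)


class TestBetweenness:
    def test_path3(self, path3):
        assert topology.betweenness(path3, normalized=False)["b"] == pytest.approx(1.0)
        assert topology.betweenness(path3, normalized=True)["b"] == pytest.approx(1.0)

    def test_star5_center_raw(self):
        G = nx.star_graph(4)  # center 0, 4 leaves -> C(4,2) pairs
        assert topology.betweenness(G, normalized=False)[0] == pytest.approx(6.0)

    def test_disconnected_raises(self, two_k3):
        with pytest.raises(ValueError):
            topology.betweenness(two_k3)


class TestEigenvector:
    def test_cycle_uniform(self):
        ce = topology.eigenvector_centrality(nx.cycle_graph(4))
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in ce.values())

    @pytest.mark.parametrize("n", [5, 9, 17])
    def test_star_ratio_closed_form(self, n):
        G = nx.star_graph(n - 1)
        ce = topology.eigenvector_centrality(G)
        # center/leaf ratio = sqrt(n-1), center has max value 1
        assert ce[0] == pytest.approx(1.0)
        assert ce[1] == pytest.approx(1 / math.sqrt(n - 1), abs=1e-9)

    def test_k4_uniform(self, k4):
        ce = topology.eigenvector_centrality(k4)
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in ce.values())


class TestSubgraphCentrality:
    def test_isolated_node_unit(self):
        G = nx.Graph([("a", "b")])
        G.add_node("iso")
        assert topology.subgraph_centrality(G)["iso"] == pytest.approx(1.0)

    def test_k2_cosh(self):
        cs = topology.subgraph_centrality(nx.complete_graph(2))
        assert cs[0] == pytest.approx(math.cosh(1.0), abs=1e-9)

    def test_k3_closed_form(self):
        cs = topology.subgraph_centrality(nx.complete_graph(3))
        expect = math.exp(2) / 3 + 2 * math.exp(-1) / 3
        assert cs[0] == pytest.approx(expect, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_identity(self, seed):
        rng = np.random.default_rng(seed)
        G = oracles.random_connected_graph(rng)
        cs = topology.subgraph_centrality(G)
        lam = np.linalg.eigvalsh(nx.to_numpy_array(G, nodelist=sorted(G)))
        assert sum(cs.values()) == pytest.approx(float(np.exp(lam).sum()), abs=1e-8)

    def test_guard(self, k4):
        with pytest.raises(ValueError, match="guard"):
            topology.subgraph_centrality(k4, n_max=3)


class TestSpectrum:
    def test_path3_clustering_bins(self, path3):
        spec = topology.spectrum(path3, {"C_k": topology.clustering(path3)})
        assert spec.loc[1, "C_k"] == 0.0 and spec.loc[2, "C_k"] == 0.0

    def test_k4_single_bin(self, k4):
        spec = topology.spectrum(k4, {})
        assert list(spec.index) == [3] and spec.loc[3, "P_k"] == 1.0

    def test_star_symmetry(self, star5):
        spec = topology.spectrum(star5, {"CN_k": topology.neighbourhood_connectivity(star5)})
        assert spec.loc[1, "CN_k"] == 4.0 and spec.loc[4, "CN_k"] == 1.0

    def test_probability_sums_to_one(self):
        G = nx.gnp_random_graph(40, 0.15, seed=2)
        spec = topology.spectrum(G, {})
        assert spec["P_k"].sum() == pytest.approx(1.0, abs=1e-12)


class TestFitPowerLaw:
    def test_exact_negative_exponent(self):
        data = {k: k**-1.0 for k in range(1, 11)}
        fit = topology.fit_power_law(data)
        assert fit.exponent == pytest.approx(-1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_exact_positive_exponent_with_prefactor(self):
        data = {k: 3.0 * k**0.5 for k in range(1, 12)}
        fit = topology.fit_power_law(data)
        assert fit.exponent == pytest.approx(0.5, abs=1e-10)
        assert fit.magnitude == pytest.approx(0.5, abs=1e-10)

    def test_zero_points_excluded(self):
        data = {1: 1.0, 2: 0.5, 3: 0.0, 4: 0.25, 5: 0.2}
        fit = topology.fit_power_law(data)
        assert fit.n_excluded == 1 and fit.n_points == 4

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="usable"):
            topology.fit_power_law({1: 1.0, 2: 0.5})

    def test_k_range_restriction(self):
        data = {k: k**-2.0 for k in range(1, 10)}
        data[20] = 5.0  # outlier outside the window
        fit = topology.fit_power_law(data, k_range=(1, 10))
        assert fit.exponent == pytest.approx(-2.0, abs=1e-10)


class TestOracleEquivalence:
    """Implementation vs brute-force/spectral oracles on random small graphs."""

    @pytest.mark.parametrize("seed", range(10))
    def test_all_centralities(self, seed):
        rng = np.random.default_rng(100 + seed)
        G = oracles.random_connected_graph(rng)
        for impl, oracle in [
            (topology.closeness(G, "scaled"), oracles.closeness_oracle(G, "scaled")),
            (topology.betweenness(G, normalized=False), oracles.betweenness_oracle(G)),
            (topology.eigenvector_centrality(G), oracles.eigenvector_oracle(G)),
            (topology.subgraph_centrality(G), oracles.subgraph_oracle(G)),
        ]:
            for node in G:
                assert impl[node] == pytest.approx(oracle[node], abs=1e-8)
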