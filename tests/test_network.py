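import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from intersoil import OtuTable, build_graph, null_model_compare, \
    recover_planted_modules, spearman_edges, topology
from intersoil.network import EdgeList


def _otu(counts: np.ndarray) -> OtuTable:
    n_s, n_o = counts.shape
    cols = [f"OTU{i}" for i in range(n_o)]
    tax = {c: f"k__B;p__Phy{i % 3}" for i, c in enumerate(cols)}
    return OtuTable(pd.DataFrame(
        counts, index=[f"s{j}" for j in range(n_s)], columns=cols), tax)


class TestSpearmanEdges:
    def test_duplicate_otu_always_connected(self, rng):
        counts = rng.integers(1, 100, size=(10, 5))
        counts[:, 1] = counts[:, 0]  # OTU1 == OTU0
        edges = spearman_edges(_otu(counts), r_min=0.9, p_max=0.05,
                               prevalence_min=0.0)
        pairs = set(map(tuple, edges.edges[["otu_i", "otu_j"]].to_numpy()))
        assert ("OTU0", "OTU1") in pairs

    def test_rmin_one_empty_on_noise(self, rng):
        counts = rng.integers(1, 100, size=(12, 8))
        edges = spearman_edges(_otu(counts), r_min=1.0, p_max=0.5,
                               prevalence_min=0.0)
        assert len(edges) == 0

    def test_matches_all_pairs_oracle(self, rng):
        counts = rng.integers(0, 60, size=(14, 15))
        counts[:, 0] = np.arange(14) * 3 + 1   # a strong monotone pair
        counts[:, 1] = np.arange(14) + 5
        otu = _otu(counts)
        edges = spearman_edges(otu, r_min=0.55, p_max=0.01,
                               prevalence_min=0.0)
        got = {tuple(e) for e in edges.edges[["otu_i", "otu_j"]].to_numpy()}
        rel = otu.relative()
        expect = set()
        for i, j in itertools.combinations(range(15), 2):
            r, p = sps.spearmanr(rel.iloc[:, i], rel.iloc[:, j])
            if abs(r) > 0.55 and p < 0.01:
                expect.add((f"OTU{i}", f"OTU{j}"))
        assert got == expect

    def test_edge_count_monotone_in_thresholds(self, rng):
        counts = rng.integers(0, 60, size=(20, 12))
        otu = _otu(counts)
        n = [len(spearman_edges(otu, r_min=r, p_max=0.5, prevalence_min=0.0))
             for r in (0.0, 0.3, 0.6, 0.9)]
        assert n == sorted(n, reverse=True)
        m = [len(spearman_edges(otu, r_min=0.0, p_max=p, prevalence_min=0.0))
             for p in (0.5, 0.1, 0.01)]
        assert m == sorted(m, reverse=True)

    def test_sample_order_invariance(self, rng):
        counts = rng.integers(0, 60, size=(16, 10))
        otu = _otu(counts)
        perm = rng.permutation(16)
        shuffled = OtuTable(otu.counts.iloc[perm], otu.taxonomy)
        e1 = spearman_edges(otu, 0.5, 0.05, 0.0).edges
        e2 = spearman_edges(shuffled, 0.5, 0.05, 0.0).edges
        pd.testing.assert_frame_equal(e1, e2)

    def test_constant_otu_skipped_with_warning(self, rng):
        counts = rng.integers(1, 60, size=(10, 6))
        counts[:, 2] = 7
        with pytest.warns(UserWarning, match="constant"):
            edges = spearman_edges(_otu(counts), 0.1, 0.9,
                                   prevalence_min=0.0, use_relative=False)
        assert "OTU2" not in set(edges.edges[["otu_i", "otu_j"]]
                                 .to_numpy().ravel())


class TestGraph:
    def test_empty_and_counts(self):
        empty = EdgeList(pd.DataFrame(
            columns=["otu_i", "otu_j", "r", "p", "sign"]), 0.6, 0.001, 0)
        assert build_graph(empty).number_of_nodes() == 0
        df = pd.DataFrame({"otu_i": ["a", "b"], "otu_j": ["b", "c"],
                           "r": [0.9, -0.8], "p": [1e-5, 1e-4],
                           "sign": ["+", "-"]})
        g = build_graph(EdgeList(df, 0.6, 0.001, 3))
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2

    def test_graphml_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 60, size=(14, 8))
        otu = _otu(counts)
        g = build_graph(spearman_edges(otu, 0.3, 0.2, 0.0), otu)
        path = tmp_path / "g.graphml"
        nx.write_graphml(g, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == \
            {frozenset(e) for e in g.edges}
        for v in g.nodes:
            assert back.nodes[v]["phylum"] == g.nodes[v]["phylum"]


class TestTopology:
    def test_complete_graph_closed_forms(self):
        t = topology(nx.complete_graph(5))
        assert t.average_clustering == pytest.approx(1.0)
        assert t.density == pytest.approx(1.0)
        assert t.average_degree == pytest.approx(4.0)
        assert t.average_path_length == pytest.approx(1.0)

    def test_two_cliques_modularity_half(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        t = topology(g)
        # hand computation: Q = sum(e_ii - a_i^2) = 2*(0.5 - 0.25)
        assert t.modularity == pytest.approx(0.5)
        assert t.n_communities == 2

    def test_path_graph_average_length(self):
        t = topology(nx.path_graph(4))
        assert t.average_path_length == pytest.approx(5.0 / 3.0)

    def test_empty_graph_explicit_nulls(self):
        t = topology(nx.Graph())
        assert t.n_nodes == 0 and t.average_degree is None

    def test_identities_hold_on_random_graphs(self, rng):
        for seed in range(5):
            g = nx.gnm_random_graph(12, 20, seed=seed)
            t = topology(g)
            assert t.density == pytest.approx(
                2 * t.n_links / (t.n_nodes * (t.n_nodes - 1)))
            assert t.average_degree == pytest.approx(
                2 * t.n_links / t.n_nodes)
            assert -0.5 <= t.modularity <= 1.0


class TestNullModel:
    def test_deterministic_under_seed(self):
        g = nx.ring_lattice = nx.watts_strogatz_graph(30, 4, 0.0, seed=1)
        a = null_model_compare(g, n_random=30, seed=5)
        b = null_model_compare(g, n_random=30, seed=5)
        assert a.z_clustering == b.z_clustering
        assert a.z_path_length == b.z_path_length

    def test_ring_lattice_clustering_and_rewiring_raises_sigma(self):
        lattice = nx.watts_strogatz_graph(50, 4, 0.0, seed=0)
        stats = null_model_compare(lattice, n_random=50, seed=0)
        # far more clustered than G(n, m), and long paths (positive z too)
        assert stats.z_clustering > 5.0
        assert stats.z_path_length > 2.0
        # rewiring shortens paths while keeping clustering: sigma rises
        rewired = nx.watts_strogatz_graph(50, 4, 0.1, seed=0)
        rew = null_model_compare(rewired, n_random=50, seed=0)
        assert rew.small_world_sigma > stats.small_world_sigma


class TestRecovery:
    def test_identical_partition_ari_one(self, blocky_otu):
        otu, truth = blocky_otu
        ari = recover_planted_modules(otu, truth, prevalence_min=0.0)
        assert ari == pytest.approx(1.0)

    def test_no_edges_reports_missing(self, blocky_otu):
        otu, truth = blocky_otu
        assert recover_planted_modules(otu, truth, r_min=0.999999,
                                       p_max=1e-12) is None
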