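"""Thresholding, graph metrics, null ensembles and omega."""

import numpy as np
import pytest

import asrtnet as a
from asrtnet import graphs as g

from conftest import brute_force_clustering, floyd_warshall_L


def complete(n):
    adj = np.ones((n, n), dtype=int)
    np.fill_diagonal(adj, 0)
    return adj


def cycle(n):
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1
    return adj


class TestThresholdAdjacency:
    def test_strict_percentile_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = np.zeros((60, 60))
        iu = np.triu_indices(60, 1)
        vals[iu] = rng.random(len(iu[0]))
        vals = vals + vals.T
        adj = a.threshold_adjacency(vals, percentile=85)
        cut = np.percentile(vals[iu], 85)
        assert adj.n_edges == int((vals[iu] > cut).sum()) == 266

    def test_constant_matrix_gives_empty_graph(self):
        with pytest.warns(UserWarning, match="empty"):
            adj = a.threshold_adjacency(np.ones((10, 10)) - np.eye(10))
        assert adj.n_edges == 0

    def test_rank_preserving_transform_invariance(self):
        rng = np.random.default_rng(1)
        vals = np.zeros((20, 20))
        iu = np.triu_indices(20, 1)
        vals[iu] = rng.random(len(iu[0]))
        vals = vals + vals.T
        a1 = a.threshold_adjacency(vals)
        a2 = a.threshold_adjacency(np.sqrt(vals))  # monotone on [0, 1]
        assert np.array_equal(a1.matrix, a2.matrix)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            a.AdjacencyNetwork(np.triu(np.ones((4, 4)), 1).astype(int))


class TestElementaryMetrics:
    def test_complete_graph(self):
        k, two_k = a.degree(complete(5))
        assert (k == 4).all() and two_k == 4
        L, disc = a.shortest_path_length(complete(5))
        assert L == 1.0 and not disc
        c_local, c = a.clustering(complete(5))
        assert (c_local == 1).all() and c == 1.0

    def test_six_cycle(self):
        k, _ = a.degree(cycle(6))
        assert (k == 2).all()
        L, _ = a.shortest_path_length(cycle(6))
        assert L == pytest.approx(1.8)  # distances 1,2,3,2,1 per node
        _, c = a.clustering(cycle(6))
        assert c == 0.0

    def test_path_graph_L(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        L, _ = a.shortest_path_length(adj)
        assert L == pytest.approx(4 / 3)

    def test_triangle_with_pendant_clustering(self):
        adj = np.zeros((4, 4), dtype=int)
        for i, j in ((0, 1), (1, 2), (0, 2), (2, 3)):
            adj[i, j] = adj[j, i] = 1
        c_local, c = a.clustering(adj)
        # nodes 0,1 fully clustered; node 2 has neighbours {0,1,3} with 1 of
        # 3 possible links (C = 1/3); pendant node 3 has k < 2 (C = 0)
        assert np.allclose(c_local, [1.0, 1.0, 1 / 3, 0.0])
        assert c == pytest.approx(7 / 12)

    def test_disconnected_pairs_excluded_and_flagged(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        L, disc = a.shortest_path_length(adj)
        assert L == 1.0 and disc

    def test_edgeless_graph_flagged(self):
        L, disc = a.shortest_path_length(np.zeros((4, 4), dtype=int))
        assert np.isnan(L) and disc

    def test_oracle_equivalence_on_random_graphs(self):
        """Exact match with triangle enumeration and Floyd-Warshall."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            p = rng.uniform(0.2, 0.8)
            adj = (rng.random((n, n)) < p).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            k, two_k = a.degree(adj)
            assert np.array_equal(k, adj.sum(axis=1))
            c_local, c_real = a.clustering(adj)
            assert np.allclose(c_local, brute_force_clustering(adj), atol=1e-12)
            if adj.sum() > 0:
                L, _ = a.shortest_path_length(adj)
                assert L == pytest.approx(floyd_warshall_L(adj), abs=1e-12)

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(7)
        adj = g.random_gnm_adjacency(25, 60, rng)
        perm = rng.permutation(25)
        padj = adj[np.ix_(perm, perm)]
        assert a.degree(adj)[1] == a.degree(padj)[1]
        assert a.shortest_path_length(adj)[0] == pytest.approx(
            a.shortest_path_length(padj)[0]
        )
        assert a.clustering(adj)[1] == pytest.approx(a.clustering(padj)[1])


class TestExports:
    def test_edgelist_and_graphml_roundtrip(self, tmp_path):
        import networkx as nx

        rng = np.random.default_rng(8)
        adj = a.AdjacencyNetwork(
            g.random_gnm_adjacency(12, 20, rng),
            node_labels=[f"E{i}" for i in range(12)],
        )
        g.write_edgelist(adj, tmp_path / "edges.txt")
        assert len((tmp_path / "edges.txt").read_text().splitlines()) == 20
        g.write_graphml(adj, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == 20
        assert set(back.nodes) == set(adj.node_labels)


class TestNullEnsemble:
    def test_complete_graph_references_are_exact(self):
        L_rand, C_latt = a.null_ensemble(8, 28, reps=5, seed=1)
        assert L_rand == 1.0 and C_latt == 1.0

    def test_lattice_without_leftover_has_zero_variance(self):
        rng = np.random.default_rng(2)
        # 2k = 4 exactly: rings 1 and 2 full, no leftover
        mats = [g.ring_lattice_adjacency(12, 24, rng) for _ in range(5)]
        assert all(np.array_equal(mats[0], m) for m in mats)
        _, c = a.clustering(mats[0])
        assert c == pytest.approx(0.5)  # known ring-lattice value at 2k=4

    def test_matches_independent_reimplementation(self):
        """Statistical agreement with a networkx-based oracle."""
        import networkx as nx

        n, m, reps = 30, 80, 150
        L_rand, C_latt = a.null_ensemble(n, m, reps=reps, seed=3)

        rng = np.random.default_rng(99)
        l_vals = []
        for r in range(reps):
            G = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            tot = cnt = 0
            for src, dists in nx.all_pairs_shortest_path_length(G):
                for dst, dd in dists.items():
                    if dst != src:
                        tot += dd
                        cnt += 1
            l_vals.append(tot / cnt)
        # same construction, independent RNG: agree within 4 standard errors
        se = np.std(l_vals) / np.sqrt(reps)
        assert abs(L_rand - np.mean(l_vals)) < 4 * se + 1e-3

        # lattice oracle: independent modular-arithmetic construction
        c_vals = []
        for r in range(reps):
            G = nx.Graph()
            G.add_nodes_from(range(n))
            ring, placed = 1, 0
            edges_per_ring = n
            while placed + edges_per_ring <= m:
                G.add_edges_from((i, (i + ring) % n) for i in range(n))
                placed += edges_per_ring
                ring += 1
            left = m - placed
            pick = rng.choice(n, size=left, replace=False)
            G.add_edges_from((int(i), int((i + ring) % n)) for i in pick)
            c_vals.append(nx.average_clustering(G))
        se_c = np.std(c_vals) / np.sqrt(reps)
        assert abs(C_latt - np.mean(c_vals)) < 4 * se_c + 1e-3

    def test_excessive_edges_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            a.null_ensemble(5, 11, reps=2)


class TestOmega:
    def test_balanced_terms_give_zero(self):
        assert a.small_world_omega(2.0, 0.5, 2.0, 0.5) == 0.0
        assert a.small_world_omega(1.0, 1.0, 1.0, 1.0) == 0.0

    def test_degenerate_lattice_clustering_rejected(self):
        with pytest.raises(ValueError, match="C_latt"):
            a.small_world_omega(2.0, 0.5, 2.0, 0.0)

    def test_topology_ordering_at_study_density(self, quiet):
        cache = g._NullCache(reps=200, seed=11)

        def omega_of(net):
            adj = a.AdjacencyNetwork(net.adjacency)
            L, _ = a.shortest_path_length(adj)
            _, C = a.clustering(adj)
            Lr, Cl = cache.get(adj.n_nodes, adj.n_edges)
            return a.small_world_omega(L, C, Lr, Cl)

        latt = omega_of(a.generate_planted_network("ring_lattice", 60, 0.15, seed=1))
        ws = omega_of(
            a.generate_planted_network("watts_strogatz", 60, 0.15, rewire_p=0.1, seed=2)
        )
        er = omega_of(a.generate_planted_network("erdos_renyi", 60, 0.15, seed=3))
        assert latt < 0 < er
        assert latt < ws < er


class TestSubjectConditionMetrics:
    def _coh(self, seed, n=20):
        rng = np.random.default_rng(seed)
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.random(len(iu[0]))
        return v + v.T

    def test_identical_segments_equal_single_segment(self):
        mats = [self._coh(1)] * 4
        gm4 = a.subject_condition_metrics(mats, reps=50, seed=2)
        gm1 = a.subject_condition_metrics(mats[:1], reps=50, seed=2)
        assert gm4.omega == pytest.approx(gm1.omega)
        assert gm4.n_segments == 4

    def test_segment_order_invariance(self):
        mats = [self._coh(s) for s in range(5)]
        g1 = a.subject_condition_metrics(mats, reps=50, seed=3)
        g2 = a.subject_condition_metrics(mats[::-1], reps=50, seed=3)
        assert g1.omega == pytest.approx(g2.omega)
        assert g1.L_real == pytest.approx(g2.L_real)

    def test_averaged_mode_thresholds_once(self):
        mats = [self._coh(s) for s in range(3)]
        gm = a.subject_condition_metrics(
            mats, reps=50, seed=4, averaging_mode="averaged"
        )
        assert gm.n_segments == 1

    def test_planted_topology_ordering_recovered_from_signals(self, quiet):
        """Lattice-like vs random planted groups keep their omega order.

        Recovery uses pooled (cross-segment) coherency before
        thresholding: per-segment estimates at this problem size are
        dominated by estimator noise, which the pooling suppresses.
        """
        omegas = {}
        cache = g._NullCache(reps=100, seed=0)
        for name, topo, rw in (("latt", "watts_strogatz", 0.02),
                               ("rand", "erdos_renyi", 0.0)):
            vals = []
            for s in range(3):
                net = a.generate_planted_network(
                    topo, 30, 0.2, rewire_p=rw, seed=10 + s
                )
                rec = a.synthesize_coupled_recording(
                    net, n_segments=30, snr=5.0, seed=20 + s
                )
                epochs = a.segment_resting(rec)
                pooled = a.pooled_band_coherency(epochs, a.DEFAULT_BANDS[0])
                adj = a.threshold_adjacency(pooled, 85)
                L, _ = a.shortest_path_length(adj)
                _, C = a.clustering(adj)
                L_rand, C_latt = cache.get(adj.n_nodes, adj.n_edges)
                vals.append(a.small_world_omega(L, C, L_rand, C_latt))
            omegas[name] = np.mean(vals)
        assert omegas["latt"] < omegas["rand"] - 0.3
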