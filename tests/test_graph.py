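"""Graph metrics: worked toys, brute-force oracles, invariances."""

import numpy as np
import pytest

import connrel as cr
from connrel.connectome import Connectome
from connrel.graph import _newman_q
import oracles


def _conn(z, atlas="t"):
    n = z.shape[0]
    return Connectome(z=z, node_ids=tuple(f"n{i+1}" for i in range(n)),
                      atlas_name=atlas)


def _toy_two_networks():
    """6 nodes, two networks of 3; within z=0.5, between z=0.1."""
    parc = cr.make_parcellation(6, [3, 3], "t")
    labels = parc.labels
    z = np.where(labels[:, None] == labels[None, :], 0.5, 0.1)
    np.fill_diagonal(z, np.nan)
    return _conn(z), parc


class TestConnectivityMeans:
    def test_within_between_toy(self):
        conn, parc = _toy_two_networks()
        per_wn, wn = cr.within_network_connectivity(conn, parc)
        per_bn, bn = cr.between_network_connectivity(conn, parc)
        assert wn == pytest.approx(0.5)
        assert bn == pytest.approx(0.1)
        assert per_wn == {"net01": pytest.approx(0.5), "net02": pytest.approx(0.5)}

    def test_singleton_network_missing(self, rng):
        parc = cr.make_parcellation(5, [4, 1], "t")
        z = np.abs(rng.normal(size=(5, 5)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        per_wn, _ = cr.within_network_connectivity(_conn(z), parc)
        assert np.isnan(per_wn["net02"])

    def test_single_network_has_no_between_pairs(self, rng):
        parc = cr.make_parcellation(4, [4], "t")
        z = np.abs(rng.normal(size=(4, 4)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        _, bn = cr.between_network_connectivity(_conn(z), parc)
        assert np.isnan(bn)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        parc = cr.make_parcellation(20, [7, 6, 4, 3], "t")
        z = oracles.random_z_matrix(rng, 20)
        conn = _conn(z)
        _, wn = cr.within_network_connectivity(conn, parc)
        _, bn = cr.between_network_connectivity(conn, parc)
        labels = parc.labels
        assert wn == pytest.approx(oracles.pair_mean_within(z, labels), abs=1e-12)
        assert bn == pytest.approx(oracles.pair_mean_between(z, labels), abs=1e-12)


class TestSegregation:
    def test_closed_form_cases(self):
        conn, parc = _toy_two_networks()
        assert cr.system_segregation(conn, parc) == pytest.approx(0.8)

    def test_zero_between_gives_one(self):
        parc = cr.make_parcellation(4, [2, 2], "t")
        z = np.full((4, 4), np.nan)
        z[0, 1] = z[1, 0] = 0.5
        z[2, 3] = z[3, 2] = 0.5
        labels_equal = cr.system_segregation(_conn(z), parc)
        assert np.isnan(labels_equal)  # between pairs all missing -> undefined

    def test_equal_means_give_zero(self):
        parc = cr.make_parcellation(4, [2, 2], "t")
        z = np.full((4, 4), 0.3)
        np.fill_diagonal(z, np.nan)
        assert cr.system_segregation(_conn(z), parc) == pytest.approx(0.0)


class TestModularity:
    def test_two_disconnected_cliques(self):
        parc = cr.make_parcellation(6, [3, 3], "t")
        labels = parc.labels
        z = np.where(labels[:, None] == labels[None, :], 0.8, 0.0)
        np.fill_diagonal(z, np.nan)
        assert cr.modularity_q(_conn(z), parc) == pytest.approx(0.5)

    def test_single_community_zero(self):
        parc = cr.make_parcellation(5, [5], "t")
        z = np.full((5, 5), 0.4)
        np.fill_diagonal(z, np.nan)
        assert cr.modularity_q(_conn(z), parc) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_louvain_dominates_atlas_partition(self, seed):
        rng = np.random.default_rng(100 + seed)
        parc = cr.make_parcellation(15, [5, 5, 5], "t")
        labels = parc.labels
        z = np.where(labels[:, None] == labels[None, :],
                     rng.uniform(0.3, 0.8, (15, 15)),
                     rng.uniform(0.0, 0.3, (15, 15)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        conn = _conn(z)
        q_atlas = cr.modularity_q(conn, parc, partition_mode="atlas")
        q_louvain = cr.modularity_q(conn, parc, partition_mode="louvain", seed=seed)
        assert q_louvain >= q_atlas - 1e-12

    def test_matches_networkx_modularity(self, rng):
        import networkx as nx

        parc = cr.make_parcellation(12, [4, 4, 4], "t")
        z = oracles.random_z_matrix(rng, 12, missing_frac=0.1)
        w = np.where(np.isfinite(z), z, 0.0)
        np.fill_diagonal(w, 0.0)
        g = nx.from_numpy_array(w)
        communities = [set(range(0, 4)), set(range(4, 8)), set(range(8, 12))]
        expected = nx.community.modularity(g, communities, weight="weight")
        assert _newman_q(w, parc.labels) == pytest.approx(expected, abs=1e-12)


class TestPathLength:
    def test_three_node_chain(self):
        z = np.full((3, 3), np.nan)
        z[0, 1] = z[1, 0] = 0.5
        z[1, 2] = z[2, 1] = 0.5
        # distances: 1-2 = 2, 2-3 = 2, 1-3 = 4 -> mean 8/3
        assert cr.characteristic_path_length(_conn(z)) == pytest.approx(8 / 3)

    def test_complete_unit_graph(self):
        z = np.ones((4, 4))
        np.fill_diagonal(z, np.nan)
        assert cr.characteristic_path_length(_conn(z)) == pytest.approx(1.0)

    def test_adding_edge_never_increases(self, rng):
        z = oracles.random_z_matrix(rng, 10, missing_frac=0.4)
        base = cr.characteristic_path_length(_conn(z))
        z2 = z.copy()
        iu = np.triu_indices(10, k=1)
        missing = [t for t in zip(*iu) if not np.isfinite(z2[t])]
        i, j = missing[0]
        z2[i, j] = z2[j, i] = 0.9
        assert cr.characteristic_path_length(_conn(z2)) <= base + 1e-12


class TestNodeMetrics:
    def test_star_strength(self):
        z = np.full((4, 4), np.nan)
        for j in (1, 2, 3):
            z[0, j] = z[j, 0] = 0.2
        s, _ = cr.nodal_strength(_conn(z))
        assert s[0] == pytest.approx(0.6)
        assert s[1] == pytest.approx(0.2)

    def test_degree_thresholding(self):
        z = np.full((5, 5), 0.05)
        np.fill_diagonal(z, np.nan)
        k, mean_k = cr.degree(_conn(z), tau=0.10)
        assert np.all(k == 0) and mean_k == 0.0
        z2 = np.full((5, 5), 0.5)
        np.fill_diagonal(z2, np.nan)
        k2, _ = cr.degree(_conn(z2), tau=0.10)
        assert np.all(k2 == 4)

    def test_density_bounds(self):
        z = np.full((5, 5), 0.5)
        np.fill_diagonal(z, np.nan)
        assert cr.density(_conn(z), tau=0.1) == pytest.approx(1.0)
        z0 = np.full((5, 5), 0.05)
        np.fill_diagonal(z0, np.nan)
        assert cr.density(_conn(z0), tau=0.1) == 0.0


class TestClustering:
    def test_triangle_is_one(self):
        z = np.full((3, 3), 0.7)
        np.fill_diagonal(z, np.nan)
        c, mean_c = cr.clustering_coefficient(_conn(z))
        assert np.allclose(c, 1.0)
        assert mean_c == pytest.approx(1.0)

    def test_star_is_zero(self):
        z = np.full((4, 4), np.nan)
        for j in (1, 2, 3):
            z[0, j] = z[j, 0] = 0.5
        c, _ = cr.clustering_coefficient(_conn(z))
        assert np.allclose(c, 0.0)


class TestEigenvector:
    def test_regular_graph_uniform(self):
        z = np.full((5, 5), 0.4)
        np.fill_diagonal(z, np.nan)
        v, mean_v = cr.eigenvector_centrality(_conn(z))
        assert np.allclose(v, 1 / np.sqrt(5))
        assert mean_v == pytest.approx(1 / np.sqrt(5))

    def test_two_node_edge(self):
        z = np.array([[np.nan, 0.3], [0.3, np.nan]])
        v, _ = cr.eigenvector_centrality(_conn(z))
        assert np.allclose(v, 1 / np.sqrt(2))


class TestOracleEquivalence:
    """Every metric against its exhaustive brute-force counterpart."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(9000 + seed)
        n = int(rng.integers(6, 21))
        sizes = [n // 2, n - n // 2]
        parc = cr.make_parcellation(n, sizes, "t")
        z = oracles.random_z_matrix(rng, n)
        conn = _conn(z)
        labels = parc.labels
        tau = 0.10

        _, wn = cr.within_network_connectivity(conn, parc)
        _, bn = cr.between_network_connectivity(conn, parc)
        assert wn == pytest.approx(oracles.pair_mean_within(z, labels), abs=1e-10)
        assert bn == pytest.approx(oracles.pair_mean_between(z, labels), abs=1e-10)
        assert cr.system_segregation(conn, parc) == pytest.approx(
            (wn - bn) / wn, abs=1e-10
        )
        assert cr.modularity_q(conn, parc) == pytest.approx(
            oracles.newman_modularity(z, labels), abs=1e-10
        )
        assert cr.characteristic_path_length(conn) == pytest.approx(
            oracles.dijkstra_cpl(z), abs=1e-10
        )
        s, _ = cr.nodal_strength(conn)
        assert np.allclose(s, oracles.strength(z), atol=1e-10)
        k, _ = cr.degree(conn, tau)
        assert np.array_equal(k, oracles.degree_count(z, tau))
        assert cr.density(conn, tau) == pytest.approx(
            oracles.edge_density(z, tau), abs=1e-10
        )
        c, _ = cr.clustering_coefficient(conn)
        assert np.allclose(c, oracles.onnela_clustering(z), atol=1e-10)
        v, _ = cr.eigenvector_centrality(conn)
        assert np.allclose(v, oracles.power_iteration_centrality(z), atol=1e-8)


class TestInvariances:
    def test_permutation_equivariance(self, rng):
        n = 14
        parc = cr.make_parcellation(n, [7, 7], "t")
        z = oracles.random_z_matrix(rng, n)
        perm = rng.permutation(n)
        zp = z[np.ix_(perm, perm)]
        node_ids = tuple(f"n{i+1}" for i in range(n))
        parc_p = cr.Parcellation(
            node_ids=node_ids,
            network_of={node_ids[i]: parc.labels[perm[i]] for i in range(n)},
            coverage_of={nid: 1.0 for nid in node_ids},
            atlas_name="t",
        )
        for fn in (cr.characteristic_path_length,):
            assert fn(_conn(zp)) == pytest.approx(fn(_conn(z)), abs=1e-10)
        _, wn = cr.within_network_connectivity(_conn(z), parc)
        _, wn_p = cr.within_network_connectivity(_conn(zp), parc_p)
        assert wn_p == pytest.approx(wn, abs=1e-10)
        s, _ = cr.nodal_strength(_conn(z))
        s_p, _ = cr.nodal_strength(_conn(zp))
        assert np.allclose(s_p, s[perm], atol=1e-10)

    def test_scale_behavior(self, rng):
        n = 12
        parc = cr.make_parcellation(n, [6, 6], "t")
        z = oracles.random_z_matrix(rng, n, missing_frac=0.1)
        conn, scaled = _conn(z), _conn(3.0 * z)
        # strength and pair means scale linearly
        assert cr.nodal_strength(scaled)[1] == pytest.approx(
            3.0 * cr.nodal_strength(conn)[1]
        )
        _, wn = cr.within_network_connectivity(conn, parc)
        _, wn_s = cr.within_network_connectivity(scaled, parc)
        assert wn_s == pytest.approx(3.0 * wn)
        # segregation, clustering (normalized), eigenvector, rescaled-tau
        # degree are scale free
        assert cr.system_segregation(scaled, parc) == pytest.approx(
            cr.system_segregation(conn, parc)
        )
        c, _ = cr.clustering_coefficient(conn)
        c_s, _ = cr.clustering_coefficient(scaled)
        assert np.allclose(c, c_s, atol=1e-12)
        v, _ = cr.eigenvector_centrality(conn)
        v_s, _ = cr.eigenvector_centrality(scaled)
        assert np.allclose(v, v_s, atol=1e-10)
        k, _ = cr.degree(conn, 0.1)
        k_s, _ = cr.degree(scaled, 0.3)
        assert np.array_equal(k, k_s)


class TestComputeAll:
    def test_row_counts_and_determinism(self):
        conn, parc = _toy_two_networks()
        frame = cr.compute_all(conn, parc)
        global_rows = frame[frame["level"] != "per_network"]
        per_net = frame[frame["level"] == "per_network"]
        assert len(global_rows) == 10
        assert len(per_net) == 2
        assert sorted(global_rows["metric"]) == sorted(cr.METRIC_NAMES)
        again = cr.compute_all(conn, parc)
        assert frame.equals(again)

    def test_missing_row_node_excluded_everywhere(self, rng):
        parc = cr.make_parcellation(8, [4, 4], "t")
        z = np.abs(rng.normal(0.4, 0.1, (8, 8)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        z[3, :] = np.nan
        z[:, 3] = np.nan
        conn = _conn(z)
        k, _ = cr.degree(conn, 0.1)
        s, _ = cr.nodal_strength(conn)
        assert k.size == 7 and s.size == 7
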