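import math

import networkx as nx
import numpy as np
import pytest

from connectopath import graph
from connectopath.io import CohortTable, ConnectivityMatrix, SubjectRecord
from conftest import floyd_warshall_reference, random_weight_matrix


def splen_of(w: np.ndarray) -> np.ndarray:
    conn = ConnectivityMatrix.from_array(w)
    return graph.shortest_paths(graph.to_distance(conn)).splen


class TestToDistance:
    def test_reciprocal_and_infinity(self, chain_matrix):
        d = graph.to_distance(chain_matrix).d
        assert d[1, 2] == 0.25
        assert d[0, 1] == 0.5
        assert d[0, 2] == np.inf
        assert np.all(np.diag(d) == 0)

    def test_homogeneity(self, triangle_matrix):
        d1 = graph.to_distance(triangle_matrix).d
        scaled = ConnectivityMatrix(
            triangle_matrix.nodes, triangle_matrix.weights * 3.0
        )
        d2 = graph.to_distance(scaled).d
        finite = np.isfinite(d1)
        np.testing.assert_allclose(d2[finite], d1[finite] / 3.0)


class TestShortestPaths:
    def test_chain(self, chain_matrix):
        splen = splen_of(chain_matrix.weights)
        assert splen[0, 1] == pytest.approx(0.5)
        assert splen[1, 2] == pytest.approx(0.25)
        assert splen[0, 2] == pytest.approx(0.75)

    def test_two_hop_dominance(self, triangle_matrix):
        splen = splen_of(triangle_matrix.weights)
        # detour via B (0.1 + 0.1) beats the direct edge (1.0)
        assert splen[0, 2] == pytest.approx(0.2)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 13))
            w = random_weight_matrix(rng, n, density=rng.uniform(0.2, 1.0))
            conn = ConnectivityMatrix.from_array(w)
            dist = graph.to_distance(conn).d
            expected = floyd_warshall_reference(dist)
            np.testing.assert_allclose(
                graph.shortest_paths(graph.to_distance(conn)).splen,
                expected,
                atol=1e-9,
            )

    def test_triangle_inequality_and_edge_upper_bound(self):
        rng = np.random.default_rng(5)
        w = random_weight_matrix(rng, 10, density=0.8)
        conn = ConnectivityMatrix.from_array(w)
        dist = graph.to_distance(conn)
        splen = graph.shortest_paths(dist).splen
        assert np.all(splen <= dist.d + 1e-12)
        for k in range(10):
            assert np.all(
                splen <= splen[:, [k]] + splen[[k], :] + 1e-12
            )


class TestWcplAndEfficiency:
    def test_complete_graph_uniform(self):
        w = np.full((5, 5), 2.0)
        np.fill_diagonal(w, 0)
        splen = graph.PathLengthMatrix(["a"] * 5, splen_of(w))
        val, n_disc = graph.wcpl(splen)
        assert val == pytest.approx(0.5)
        assert n_disc == 0
        assert graph.global_efficiency(splen) == pytest.approx(2.0)

    def test_chain_hand_sum(self, chain_matrix):
        splen = graph.shortest_paths(graph.to_distance(chain_matrix))
        val, _ = graph.wcpl(splen)
        assert val == pytest.approx((0.5 + 0.25 + 0.75) / 3)

    def test_triangle_hand_sums(self, triangle_matrix):
        splen = graph.shortest_paths(graph.to_distance(triangle_matrix))
        val, _ = graph.wcpl(splen)
        assert val == pytest.approx((0.1 + 0.1 + 0.2) / 3)
        assert graph.global_efficiency(splen) == pytest.approx((10 + 10 + 5) / 3)

    def test_disconnected_pair_counted(self, chain_matrix):
        w = np.zeros((4, 4))
        w[:3, :3] = chain_matrix.weights
        splen = graph.shortest_paths(
            graph.to_distance(ConnectivityMatrix.from_array(w))
        )
        val, n_disc = graph.wcpl(splen)
        assert n_disc == 3
        assert val == pytest.approx(0.5)

    def test_empty_network_error(self):
        w = np.zeros((3, 3))
        splen = graph.shortest_paths(
            graph.to_distance(ConnectivityMatrix.from_array(w))
        )
        with pytest.raises(graph.EmptyNetworkError):
            graph.wcpl(splen)
        assert graph.global_efficiency(splen) == 0.0

    def test_am_hm_inequality(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            w = random_weight_matrix(rng, n, density=1.0)
            splen = graph.PathLengthMatrix([""] * n, splen_of(w))
            val, n_disc = graph.wcpl(splen)
            assert n_disc == 0
            assert graph.global_efficiency(splen) >= 1.0 / val - 1e-12

    def test_am_hm_equality_iff_uniform(self):
        w = np.full((4, 4), 5.0)
        np.fill_diagonal(w, 0)
        splen = graph.PathLengthMatrix([""] * 4, splen_of(w))
        val, _ = graph.wcpl(splen)
        assert graph.global_efficiency(splen) == pytest.approx(1.0 / val)


class TestClustering:
    def test_uniform_triangle(self):
        w = np.array([[0.0, 3, 3], [3, 0, 3], [3, 3, 0]])
        assert graph.clustering_coefficient(
            ConnectivityMatrix.from_array(w)
        ) == pytest.approx(1.0)

    def test_path_graph_no_triangles(self, chain_matrix):
        assert graph.clustering_coefficient(chain_matrix) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        w = random_weight_matrix(rng, 8, density=0.6)
        conn = ConnectivityMatrix.from_array(w)
        scaled = ConnectivityMatrix.from_array(w * 7.3)
        assert graph.clustering_coefficient(conn) == pytest.approx(
            graph.clustering_coefficient(scaled)
        )


def ring_lattice(n: int = 30, k: int = 4) -> ConnectivityMatrix:
    g = nx.watts_strogatz_graph(n, k, p=0.0)
    w = nx.to_numpy_array(g) * 2.0
    return ConnectivityMatrix.from_array(w)


class TestSmallWorldness:
    def test_plain_ratio(self):
        assert graph.small_worldness(1.0, 0.5, mode="plain") == 2.0

    def test_self_normalization(self, triangle_matrix):
        cc = graph.clustering_coefficient(triangle_matrix)
        val, _ = graph.wcpl(
            graph.shortest_paths(graph.to_distance(triangle_matrix))
        )
        swn = graph.small_worldness(
            cc, val, mode="normalized", null_ensemble=[triangle_matrix]
        )
        assert swn == pytest.approx(1.0)

    def test_zero_wcpl_rejected(self):
        with pytest.raises(ValueError):
            graph.small_worldness(1.0, 0.0)

    def test_lattice_normalized_above_one(self):
        lattice = ring_lattice()
        nulls = [
            graph.rewire_null(lattice, n_swaps=10 * 60, seed=s) for s in range(20)
        ]
        cc = graph.clustering_coefficient(lattice)
        val, _ = graph.wcpl(graph.shortest_paths(graph.to_distance(lattice)))
        swn = graph.small_worldness(cc, val, mode="normalized", null_ensemble=nulls)
        assert swn > 1.0


class TestRewireNull:
    def test_degree_sequence_and_weight_multiset_preserved(self):
        rng = np.random.default_rng(17)
        w = random_weight_matrix(rng, 12, density=0.5)
        conn = ConnectivityMatrix.from_array(w)
        null = graph.rewire_null(conn, n_swaps=50, seed=1)
        deg = lambda c: sorted((c.weights > 0).sum(axis=0))
        assert deg(null) == deg(conn)
        iu = np.triu_indices(12, k=1)
        orig = sorted(w[iu][w[iu] > 0])
        new = sorted(null.weights[iu][null.weights[iu] > 0])
        np.testing.assert_allclose(new, orig)

    def test_determinism(self):
        lattice = ring_lattice()
        a = graph.rewire_null(lattice, n_swaps=100, seed=42)
        b = graph.rewire_null(lattice, n_swaps=100, seed=42)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_triangle_count_decreases_in_most_seeds(self):
        lattice = ring_lattice()
        n_tri = lambda c: int(
            np.trace(np.linalg.matrix_power((c.weights > 0).astype(int), 3)) // 6
        )
        base = n_tri(lattice)
        n_edges = int((lattice.weights > 0).sum() // 2)
        decreased = sum(
            n_tri(graph.rewire_null(lattice, n_swaps=100 * n_edges, seed=s)) < base
            for s in range(20)
        )
        assert decreased >= 17

    def test_impossible_swap_returns_input(self, caplog):
        # complete graph admits no degree-preserving swap
        w = np.full((4, 4), 1.0)
        np.fill_diagonal(w, 0)
        conn = ConnectivityMatrix.from_array(w)
        with caplog.at_level("WARNING", logger="connectopath"):
            null = graph.rewire_null(conn, n_swaps=5, seed=0)
        np.testing.assert_array_equal(null.weights, conn.weights)


class TestMetricInvariances:
    def test_homogeneity_of_wcpl_ge_swn(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            w = random_weight_matrix(rng, n, density=0.9)
            c = rng.uniform(0.5, 5.0)
            m1 = graph.subject_metrics("a", ConnectivityMatrix.from_array(w))
            m2 = graph.subject_metrics("a", ConnectivityMatrix.from_array(w * c))
            assert m2.wcpl == pytest.approx(m1.wcpl / c)
            assert m2.ge == pytest.approx(m1.ge * c)
            assert m2.cc == pytest.approx(m1.cc)
            assert m2.swn == pytest.approx(m1.swn * c)

    def test_monotonicity_adding_tracts(self):
        rng = np.random.default_rng(13)
        w = random_weight_matrix(rng, 9, density=0.6)
        base = splen_of(w)
        ge_base = graph.global_efficiency(graph.PathLengthMatrix([""] * 9, base))
        for _ in range(10):
            i, j = rng.integers(0, 9, 2)
            if i == j:
                continue
            w2 = w.copy()
            w2[i, j] = w2[j, i] = w2[i, j] + rng.uniform(0.5, 5.0)
            new = splen_of(w2)
            finite = np.isfinite(base)
            assert np.all(new[finite] <= base[finite] + 1e-12)
            ge_new = graph.global_efficiency(graph.PathLengthMatrix([""] * 9, new))
            assert ge_new >= ge_base - 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(37)
        w = random_weight_matrix(rng, 10, density=0.7)
        conn = ConnectivityMatrix.from_array(w)
        perm = conn.permuted(rng.permutation(10))
        m1 = graph.subject_metrics("a", conn)
        m2 = graph.subject_metrics("a", perm)
        for attr in ("wcpl", "cc", "ge", "swn"):
            assert getattr(m1, attr) == pytest.approx(getattr(m2, attr))


def _cohort_of(matrices: dict) -> CohortTable:
    recs = [
        SubjectRecord(
            subject_id=sid, group="ptsd", mdd=False, age=50.0, sex="male",
            education="bachelor", body_mass=28.0, pcl_total=50.0,
            re_experiencing=1, avoidance=1, hyperarousal=1, negative_affect=1,
            overall=1,
        )
        for sid in matrices
    ]
    return CohortTable(recs, matrices)


class TestCohortMetrics:
    def test_identical_matrices_identical_rows(self, triangle_matrix):
        cohort = _cohort_of({f"s{i}": triangle_matrix for i in range(3)})
        df = graph.metrics_for_cohort(cohort)
        assert len(df) == 3
        assert df["wcpl"].nunique() == 1
        assert df["cc"].nunique() == 1

    def test_error_carries_subject_id(self):
        empty = ConnectivityMatrix.from_array(np.zeros((3, 3)))
        cohort = _cohort_of({"s_bad": empty})
        with pytest.raises(graph.EmptyNetworkError, match="s_bad"):
            graph.metrics_for_cohort(cohort)

    def test_log_swn_natural_log(self, triangle_matrix):
        df = graph.metrics_for_cohort(_cohort_of({"s": triangle_matrix}))
        assert df["log_swn"][0] == pytest.approx(math.log(df["swn"][0]))
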