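"""Graph measures against hand-computed values and brute-force oracles."""

import numpy as np
import pytest

import oracles
from eegfc.graph import (
    GraphConfig,
    NullModelError,
    WeightedGraph,
    all_measures,
    assortativity,
    clustering_transitivity_local_efficiency,
    degree_strength,
    default_degree_threshold,
    modularity,
    modularity_q,
    shortest_path_measures,
    small_worldness,
)
from conftest import random_weighted_graph


def triangle(w=1.0):
    m = np.array([[0, 1, 1], [1, 0, w], [1, w, 0]], dtype=float)
    return WeightedGraph(m)


def star(n=5):
    m = np.zeros((n, n))
    m[0, 1:] = m[1:, 0] = 1.0
    return WeightedGraph(m)


class TestDegreeStrength:
    def test_unit_triangle(self):
        deg, st, avg_d, avg_s = degree_strength(triangle(), 0.0)
        np.testing.assert_array_equal(deg, [2, 2, 2])
        np.testing.assert_array_equal(st, [2, 2, 2])
        assert avg_d == 2 and avg_s == 2

    def test_threshold_counts_only_strong_edges(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.6
        m[0, 2] = m[2, 0] = 0.4
        m[0, 3] = m[3, 0] = 0.2
        deg, st, _, _ = degree_strength(WeightedGraph(m), 0.5)
        assert deg[0] == 1  # only the 0.6 edge passes
        assert st[0] == pytest.approx(1.2)  # strength is unthresholded

    def test_empty_graph(self):
        deg, st, avg_d, avg_s = degree_strength(WeightedGraph(np.zeros((5, 5))), 0.0)
        assert avg_d == 0 and avg_s == 0

    def test_method_default_thresholds(self):
        assert default_degree_threshold("coherence") == 0.5
        assert default_degree_threshold("pli") == 0.05


class TestShortestPaths:
    def test_three_node_path_hand_values(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[1, 2] = m[2, 1] = 1.0
        cpl, radius, diameter, geff, nodal = shortest_path_measures(WeightedGraph(m))
        assert cpl == pytest.approx(4 / 3)
        assert geff == pytest.approx(5 / 6)
        assert (radius, diameter) == (1.0, 2.0)
        np.testing.assert_allclose(nodal, [(1 + 0.5) / 2, 1.0, (1 + 0.5) / 2])

    def test_complete_unit_graph(self):
        m = 1.0 - np.eye(4)
        cpl, radius, diameter, geff, _ = shortest_path_measures(WeightedGraph(m))
        assert cpl == radius == diameter == geff == 1.0

    def test_doubling_weights_halves_distances(self, rng):
        w = random_weighted_graph(rng, n=6, p_edge=0.8)
        cpl1, _, _, e1, _ = shortest_path_measures(WeightedGraph(w))
        cpl2, _, _, e2, _ = shortest_path_measures(WeightedGraph(2 * w))
        assert cpl2 == pytest.approx(cpl1 / 2)
        assert e2 == pytest.approx(2 * e1)


class TestClustering:
    def test_unit_triangle_fully_clustered(self):
        cl, mcl, tr, le, mle = clustering_transitivity_local_efficiency(triangle())
        np.testing.assert_allclose(cl, 1.0)
        assert tr == pytest.approx(1.0)

    def test_star_is_triangle_free(self):
        cl, mcl, tr, le, mle = clustering_transitivity_local_efficiency(star())
        np.testing.assert_allclose(cl, 0.0)
        assert tr == 0.0 and mle == 0.0

    def test_weighted_triangle_geometric_mean_form(self):
        """Triangle with weights (1, 1, w): every node's clustering is
        w^(1/3), per the geometric-mean triangle formulation."""
        w = 0.3
        cl, _, tr, _, _ = clustering_transitivity_local_efficiency(triangle(w))
        np.testing.assert_allclose(cl, w ** (1 / 3), rtol=1e-12)
        assert tr == pytest.approx(w ** (1 / 3), rel=1e-12)


class TestModularity:
    def test_two_disjoint_triangles_q_half(self):
        m = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            m[a, b] = m[b, a] = 1.0
        q, labels = modularity(WeightedGraph(m), seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len({labels[0], labels[3]}) == 2  # the two triangles split
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_complete_graph_has_no_structure(self):
        q, _ = modularity(WeightedGraph(1.0 - np.eye(5)), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_reported_q_matches_partition(self, rng):
        w = random_weighted_graph(rng, n=6, p_edge=0.7)
        if w.sum() == 0:
            pytest.skip("empty draw")
        q, labels = modularity(WeightedGraph(w), seed=1)
        assert q == pytest.approx(modularity_q(w, labels), abs=1e-15)

    def test_deterministic_given_seed(self, rng):
        w = random_weighted_graph(rng, n=6, p_edge=0.7)
        q1, l1 = modularity(WeightedGraph(w), seed=42)
        q2, l2 = modularity(WeightedGraph(w), seed=42)
        assert q1 == q2
        np.testing.assert_array_equal(l1, l2)

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValueError, match="zero-weight"):
            modularity(WeightedGraph(np.zeros((4, 4))))


class TestAssortativity:
    def test_unit_star_is_perfectly_disassortative(self):
        assert assortativity(star(5)) == pytest.approx(-1.0)

    def test_edge_regular_graph_undefined(self):
        # triangle: every edge joins strength-2 endpoints -> zero variance
        assert np.isnan(assortativity(triangle()))

    def test_two_disjoint_unit_edges_undefined(self):
        # all endpoint strengths equal 1 -> degenerate variance -> NaN
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 1.0
        assert np.isnan(assortativity(WeightedGraph(m)))


class TestSmallWorldness:
    def test_ring_lattice_with_shortcuts_exceeds_one(self):
        """The canonical small-world regime: a ring lattice (high C) with a
        few shortcuts (short L) scores sigma > 1 against rewired nulls."""
        n = 20
        m = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                j = (i + d) % n
                m[i, j] = m[j, i] = 1.0
        rng = np.random.default_rng(0)
        for _ in range(3):  # a few shortcuts
            i, j = rng.choice(n, 2, replace=False)
            m[i, j] = m[j, i] = 1.0
        sigma, c_rand, l_rand = small_worldness(
            WeightedGraph(m), n_nulls=50, seed=0
        )
        assert sigma > 1.1

    def test_deterministic_given_seed(self, rng):
        w = random_weighted_graph(rng, n=8, p_edge=0.9, w_lo=0.3)
        s1 = small_worldness(WeightedGraph(w), n_nulls=20, seed=5)
        s2 = small_worldness(WeightedGraph(w), n_nulls=20, seed=5)
        assert s1 == s2

    def test_random_graph_scores_near_one_against_own_ensemble(self):
        rng = np.random.default_rng(8)
        w = random_weighted_graph(rng, n=12, p_edge=0.5, w_lo=0.2)
        sigmas = []
        for seed in range(5):
            sigma, _, _ = small_worldness(WeightedGraph(w), n_nulls=30, seed=seed)
            sigmas.append(sigma)
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.25)

    def test_small_or_disconnected_graph_rejected(self):
        with pytest.raises(NullModelError):
            small_worldness(triangle(), n_nulls=5)
        m = np.zeros((6, 6))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(NullModelError):
            small_worldness(WeightedGraph(m), n_nulls=5)


class TestAllMeasures:
    def test_complete_k19_trivial_values(self):
        from eegfc.connectivity import ConnectivityMatrix
        from eegfc.signal import get_band

        m = ConnectivityMatrix(
            values=1.0 - np.eye(19),
            method="coherence",
            band=get_band("alpha"),
            subject_id="s",
            condition="pre",
            n_epochs_used=10,
        )
        ms = all_measures(
            m, GraphConfig(degree_threshold=0.5, n_nulls=5, seed=0)
        )
        g = ms.global_measures
        assert g["average_degree"] == 18
        assert g["average_strength"] == 18
        assert g["clustering_coefficient"] == pytest.approx(1.0)
        assert g["global_efficiency"] == pytest.approx(1.0)
        assert g["modularity"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(ms.nodal_measures["degree"], 18)

    def test_every_measure_finite_or_flagged(self, rng):
        """Totality: no silent NaN outside the documented assortativity
        degeneracy."""
        from eegfc.connectivity import ConnectivityMatrix
        from eegfc.signal import get_band

        w = random_weighted_graph(rng, n=19, p_edge=0.9, w_lo=0.2, w_hi=0.9)
        m = ConnectivityMatrix(
            values=w, method="pli", band=get_band("beta"),
            subject_id="s", condition="post", n_epochs_used=10,
        )
        ms = all_measures(m, GraphConfig(degree_threshold=0.05, n_nulls=5, seed=0))
        for name, val in ms.global_measures.items():
            if name == "assortativity":
                continue
            assert np.isfinite(val), name


class TestOracleEquivalence:
    """Property suite: every measure matches its brute-force oracle on
    randomized small graphs."""

    @pytest.mark.parametrize("stream", [0, 1])
    def test_measures_match_oracles_on_random_graphs(self, stream):
        rng = np.random.default_rng(100 + stream)
        checked = 0
        while checked < 100:
            w = random_weighted_graph(rng)
            g = WeightedGraph(w)
            pm = oracles.path_measures(w)
            cpl, radius, diameter, geff, nodal = shortest_path_measures(g)
            if np.isfinite(pm["characteristic_path_length"]):
                assert cpl == pytest.approx(
                    pm["characteristic_path_length"], rel=1e-9
                )
            assert geff == pytest.approx(pm["global_efficiency"], rel=1e-9, abs=1e-12)
            assert radius == pytest.approx(pm["radius"], rel=1e-9, abs=1e-12)
            assert diameter == pytest.approx(pm["diameter"], rel=1e-9, abs=1e-12)
            np.testing.assert_allclose(
                nodal, pm["nodal_global_efficiency"], rtol=1e-9, atol=1e-12
            )

            cm = oracles.clustering_measures(w)
            cl, mcl, tr, le, mle = clustering_transitivity_local_efficiency(g)
            np.testing.assert_allclose(cl, cm["nodal_clustering"], rtol=1e-9)
            assert tr == pytest.approx(cm["transitivity"], rel=1e-9, abs=1e-12)
            np.testing.assert_allclose(
                le, cm["nodal_local_efficiency"], rtol=1e-9, atol=1e-12
            )

            a_impl = assortativity(g)
            a_oracle = oracles.edge_strength_assortativity(w)
            assert (np.isnan(a_impl) and np.isnan(a_oracle)) or a_impl == (
                pytest.approx(a_oracle, rel=1e-8, abs=1e-10)
            )

            if w.sum() > 0:
                q_impl, _ = modularity(g, seed=0)
                assert q_impl == pytest.approx(
                    oracles.exhaustive_modularity(w), rel=1e-9, abs=1e-12
                )
            checked += 1

    def test_degree_strength_match_oracle(self, rng):
        for _ in range(50):
            w = random_weighted_graph(rng)
            thr = float(rng.uniform(0, 0.8))
            deg, st, _, _ = degree_strength(WeightedGraph(w), thr)
            o_deg, o_st = oracles.degree_strength(w, thr)
            np.testing.assert_array_equal(deg, o_deg)
            np.testing.assert_allclose(st, o_st, rtol=1e-12)
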