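"""Permutation test, FDR, t-test, normalization and edge-ranking checks."""

import numpy as np
import pandas as pd
import pytest

from eegfc.connectivity import ConnectivityMatrix
from eegfc.signal import get_band
from eegfc.stats import (
    PairedSample,
    compare_measures,
    correlate_changes,
    exhaustive_sign_flip_p,
    fdr_adjust,
    node_increase_scores,
    normalize_changes,
    paired_permutation_test,
    paired_t_test,
    top_increased_edges,
)


def _sample(pre, post):
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    ids = tuple(f"s{i}" for i in range(len(pre)))
    return PairedSample(ids, pre, post)


class TestPairedPermutation:
    def test_all_zero_differences_give_p_one(self):
        obs, p = paired_permutation_test(_sample([1, 2, 3], [1, 2, 3]))
        assert obs == 0.0 and p == 1.0

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self, rng):
        """At n=5..8 the Monte-Carlo p matches the exact 2^n sign-flip p
        within Monte-Carlo error."""
        for n in (5, 6, 8):
            d = rng.normal(0.4, 1.0, size=n)
            s = _sample(np.zeros(n), d)
            exact = exhaustive_sign_flip_p(d)
            _, p_mc = paired_permutation_test(s, n_perm=20000, seed=0)
            # MC standard error ~ sqrt(p(1-p)/n_perm)
            se = np.sqrt(exact * (1 - exact) / 20000)
            assert abs(p_mc - exact) < 4 * se + 1e-4, (n, p_mc, exact)

    def test_strong_consistent_effect_is_significant(self, rng):
        d = 1.0 + 0.01 * rng.normal(size=12)
        _, p = paired_permutation_test(_sample(np.zeros(12), d), seed=1)
        assert p < 0.01

    def test_seeded_reproducibility(self, rng):
        d = rng.normal(size=10)
        s = _sample(np.zeros(10), d)
        assert paired_permutation_test(s, seed=3) == paired_permutation_test(s, seed=3)


class TestFDR:
    def test_step_up_hand_example(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_classic_staircase(self):
        # hand evaluation: q_i = min_{j>=i} p_j * m / j
        p = np.array([0.005, 0.04, 0.03, 0.2])
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, [0.02, 0.053333333, 0.053333333, 0.2])

    def test_single_and_tied_pvalues(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.03])), [0.03])
        np.testing.assert_allclose(fdr_adjust(np.full(5, 0.02)), np.full(5, 0.02))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))

    def test_q_dominates_p(self, rng):
        p = rng.uniform(0.001, 1.0, 30)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)


class TestPairedT:
    def test_textbook_three_pair_example(self):
        """d = (2, 4, 6): t = dbar / (s_d / sqrt(n)) = 4 / (2/sqrt(3))."""
        res = paired_t_test(_sample([1.0, 2.0, 3.0], [3.0, 6.0, 9.0]))
        expected_t = 4.0 / (2.0 / np.sqrt(3.0))
        assert res["t"] == pytest.approx(expected_t, rel=1e-12)
        from scipy import stats as sstats

        assert res["p"] == pytest.approx(2 * sstats.t.sf(expected_t, df=2), rel=1e-12)

    def test_identical_samples_flagged_degenerate(self):
        res = paired_t_test(_sample([1.0, 2.0], [1.0, 2.0]))
        assert res["degenerate"] and np.isnan(res["t"])

    def test_summary_statistics_layout(self):
        res = paired_t_test(_sample([5.0, 6.0, 7.0], [4.0, 5.0, 5.8]))
        assert res["mean_pre"] == pytest.approx(6.0)
        assert res["sd_pre"] == pytest.approx(1.0)


class TestNormalizeAndCorrelate:
    def test_arithmetic_example(self):
        np.testing.assert_allclose(normalize_changes(np.array([1, 2, 3])), [-1, 0, 1])

    def test_output_standardized_and_affine_invariant(self, rng):
        x = rng.normal(2.0, 5.0, 20)
        z = normalize_changes(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(normalize_changes(3.0 * x - 7.0), z, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_changes(np.full(5, 2.0))

    def test_identity_and_orthogonal_correlations(self, rng):
        x = rng.normal(size=15)
        res = correlate_changes(x, x.copy())
        assert res.r == pytest.approx(1.0)
        y = rng.normal(size=15)
        y -= (y @ x) / (x @ x) * x  # orthogonalize, then remove mean effect
        y -= y.mean()
        x0 = x - x.mean()
        y0 = y - (y @ x0) / (x0 @ x0) * x0
        res = correlate_changes(x, y0)
        assert res.r == pytest.approx(0.0, abs=1e-9)

    def test_misaligned_vectors_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate_changes(rng.normal(size=5), rng.normal(size=6))


def _matrix(values, method="coherence", band="alpha", condition="pre"):
    labels = tuple(chr(65 + i) for i in range(values.shape[0]))
    return ConnectivityMatrix(
        values=values, method=method, band=get_band(band), subject_id="group",
        condition=condition, n_epochs_used=10, channel_labels=labels,
    )


class TestEdgeRanking:
    def test_single_perturbed_edge_ranks_first(self, rng):
        n = 6
        base = np.zeros((n, n))
        post = base.copy()
        post[1, 4] = post[4, 1] = 0.3
        edges = top_increased_edges(_matrix(base), _matrix(post, condition="post"), k=3)
        assert (edges.iloc[0]["chan_i"], edges.iloc[0]["chan_j"]) == ("B", "E")
        assert edges.iloc[0]["increase"] == pytest.approx(0.3)

    def test_equal_matrices_flagged_all_zero_in_tie_order(self):
        m = np.zeros((4, 4))
        edges = top_increased_edges(_matrix(m), _matrix(m, condition="post"), k=3)
        assert edges["all_zero"].all()
        assert list(edges["chan_i"]) == ["A", "A", "A"]
        assert list(edges["chan_j"]) == ["B", "C", "D"]

    def test_full_ranking_matches_brute_force_sort(self, rng):
        n = 7
        pre = np.zeros((n, n))
        vals = rng.uniform(0, 1, (n, n))
        post = np.triu(vals, 1)
        post = post + post.T
        k = n * (n - 1) // 2
        edges = top_increased_edges(_matrix(pre), _matrix(post, condition="post"), k=k)
        expected = sorted(
            (
                (post[i, j], i, j)
                for i in range(n)
                for j in range(i + 1, n)
            ),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        got = list(zip(edges["increase"], edges["chan_i"], edges["chan_j"]))
        for (w, i, j), (gw, gi, gj) in zip(expected, got):
            assert gw == pytest.approx(w)
            assert (gi, gj) == (chr(65 + i), chr(65 + j))

    def test_mismatched_matrices_rejected(self):
        a = _matrix(np.zeros((4, 4)), band="alpha")
        b = _matrix(np.zeros((4, 4)), band="beta", condition="post")
        with pytest.raises(ValueError):
            top_increased_edges(a, b)


class TestNodeScores:
    def test_single_edge_scores_both_endpoints(self):
        edges = pd.DataFrame(
            {"chan_i": ["A"], "chan_j": ["B"], "increase": [0.1],
             "weight_post": [0.7], "all_zero": [False]}
        )
        s = node_increase_scores(edges)
        assert s["A"] == s["B"] == pytest.approx(0.7)

    def test_hub_accumulates_all_incident_weights(self):
        edges = pd.DataFrame(
            {
                "chan_i": ["H", "H", "H"],
                "chan_j": ["A", "B", "C"],
                "increase": [0.1, 0.2, 0.3],
                "weight_post": [0.5, 0.6, 0.7],
                "all_zero": False,
            }
        )
        s = node_increase_scores(edges)
        assert s["H"] == pytest.approx(1.8)
        assert s.index[0] == "H"

    def test_scores_match_direct_incidence_sum(self, rng):
        labels = [chr(65 + i) for i in range(8)]
        rows = []
        seen = set()
        while len(rows) < 10:
            i, j = sorted(rng.choice(8, 2, replace=False))
            if (i, j) in seen:
                continue
            seen.add((i, j))
            rows.append(
                {"chan_i": labels[i], "chan_j": labels[j],
                 "increase": rng.uniform(), "weight_post": rng.uniform(),
                 "all_zero": False}
            )
        edges = pd.DataFrame(rows)
        s = node_increase_scores(edges, top_n=16)
        direct = {}
        for row in rows:
            for ch in (row["chan_i"], row["chan_j"]):
                direct[ch] = direct.get(ch, 0.0) + row["weight_post"]
        for ch, val in direct.items():
            assert s[ch] == pytest.approx(val)


class TestCompareMeasures:
    def test_tidy_comparison_layout_and_fdr_families(self, rng):
        rows = []
        for sid in range(8):
            for cond in ("pre", "post"):
                for measure in ("m1", "m2"):
                    for band in ("alpha", "beta"):
                        bump = 0.8 if (cond, measure, band) == ("post", "m1", "alpha") else 0.0
                        rows.append(
                            {"subject_id": f"s{sid}", "condition": cond,
                             "measure": measure, "band": band,
                             "value": rng.normal() * 0.1 + bump}
                        )
        table = pd.DataFrame(rows)
        out = compare_measures(table, n_perm=500, seed=0)
        assert set(out["measure"]) == {"m1", "m2"}
        assert len(out) == 4
        row = out[(out.measure == "m1") & (out.band == "alpha")].iloc[0]
        assert row["p_perm"] < 0.05
        assert np.all(out["q_fdr"] >= out["p_perm"] - 1e-12)

    def test_reproducible_given_seed(self, rng):
        rows = [
            {"subject_id": f"s{i}", "condition": c, "measure": "m", "band": "alpha",
             "value": rng.normal()}
            for i in range(6) for c in ("pre", "post")
        ]
        t = pd.DataFrame(rows)
        a = compare_measures(t, n_perm=200, seed=7)
        b = compare_measures(t, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)
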