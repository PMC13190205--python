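"""Interaction embedding and graph kernels (PGK, WL, SP), with
independent brute-force oracles and Mercer-property checks."""

import math
from collections import Counter

import numpy as np
import pytest

from pgk.encoding import PerceptualTraitVector
from pgk.graphs import CANONICAL_PAIRS, build_deviation_graph
from pgk.kernels import (
    check_psd,
    embed,
    embedding_matrix,
    gram_matrix,
    median_sigma,
    pgk_pair,
    sp_kernel,
    wl_kernel,
)
from pgk.kernels import _sp_features, _wl_feature_maps, _feature_gram
from conftest import HEALTHY, STRESS, random_graphs


class TestEmbed:
    def test_canonical_coordinates(self, healthy_vector):
        g = build_deviation_graph(healthy_vector, epsilon=0.0)
        phi = embed(g)
        assert phi.coordinates.shape == (15,)
        lc_wi = CANONICAL_PAIRS.index(("LC", "WI"))
        assert phi.coordinates[lc_wi] == pytest.approx(0.80)

    def test_pruned_graph_embeds_to_zero(self):
        vec = PerceptualTraitVector(owner_id="v", intensities=np.full(6, 0.3))
        g = build_deviation_graph(vec, epsilon=0.2)
        assert np.all(embed(g).coordinates == 0.0)

    def test_duplicate_graphs_embed_identically(self, stress_vector):
        g1 = build_deviation_graph(stress_vector, epsilon=0.1)
        g2 = build_deviation_graph(stress_vector, epsilon=0.1)
        assert np.array_equal(embed(g1).coordinates, embed(g2).coordinates)

    def test_augmented_mode_appends_intensities(self, healthy_vector):
        g = build_deviation_graph(healthy_vector, epsilon=0.0)
        phi = embed(g, augmented=True)
        assert phi.coordinates.shape == (21,)
        assert np.allclose(phi.coordinates[15:], healthy_vector.intensities)


class TestPgkPair:
    def test_self_similarity_is_one(self, healthy_vector):
        phi = embed(build_deviation_graph(healthy_vector, 0.0))
        assert pgk_pair(phi, phi, sigma=0.5) == pytest.approx(1.0)

    def test_analytic_value_at_two_sigma_squared(self):
        a = np.zeros(15)
        b = np.zeros(15)
        b[0] = 1.0  # ||a-b||^2 = 1 = 2 sigma^2 for sigma = 1/sqrt(2)
        sigma = 1.0 / math.sqrt(2.0)
        assert pgk_pair(a, b, sigma=sigma) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_reference_graphs_match_hand_computation(
        self, healthy_vector, stress_vector
    ):
        """RBF similarity between the healthy and stressed reference
        embeddings equals an independent arithmetic computation over the
        15 coordinate differences."""
        gh = build_deviation_graph(healthy_vector, 0.0)
        gs = build_deviation_graph(stress_vector, 0.0)
        # independent oracle: plain python loops, no package code
        d2 = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                wh = abs(HEALTHY[i] - HEALTHY[j])
                ws = abs(STRESS[i] - STRESS[j])
                d2 += (wh - ws) ** 2
        expected = math.exp(-d2 / 2.0)
        assert pgk_pair(embed(gh), embed(gs), sigma=1.0) == pytest.approx(expected, rel=1e-12)

    def test_linear_variant_is_inner_product(self, healthy_vector, stress_vector):
        a = embed(build_deviation_graph(healthy_vector, 0.0)).coordinates
        b = embed(build_deviation_graph(stress_vector, 0.0)).coordinates
        assert pgk_pair(a, b, variant="linear") == pytest.approx(float(a @ b))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            pgk_pair(np.zeros(15), np.zeros(15), sigma=0.0)


class TestGramMatrix:
    def test_identical_graphs_give_all_ones(self, healthy_vector):
        graphs = [build_deviation_graph(healthy_vector, 0.05) for _ in range(4)]
        km = gram_matrix(graphs, sigma=1.0)
        assert np.allclose(km.values, 1.0)

    def test_linear_gram_equals_phi_t_phi(self):
        graphs = random_graphs(8, seed=1)
        X = embedding_matrix(graphs)
        km = gram_matrix(graphs, variant="linear")
        assert np.allclose(km.values, X @ X.T)

    def test_rbf_diagonal_is_unit(self):
        km = gram_matrix(random_graphs(10, seed=2), sigma=0.4)
        assert np.allclose(np.diag(km.values), 1.0)

    def test_median_heuristic_bandwidth_recorded(self):
        graphs = random_graphs(12, seed=3)
        km = gram_matrix(graphs, sigma="median")
        assert km.spec["sigma"] == pytest.approx(median_sigma(embedding_matrix(graphs)))

    def test_inconsistent_trait_sets_rejected(self, healthy_vector):
        g1 = build_deviation_graph(healthy_vector, 0.0)
        other = PerceptualTraitVector(
            owner_id="o",
            intensities=np.full(4, 0.5),
            traits=("A", "B", "C", "D"),
        )
        g2 = build_deviation_graph(other, 0.0)
        with pytest.raises(ValueError, match="trait set"):
            gram_matrix([g1, g2])


def naive_wl_kernel(labels_list, adj_list, h):
    """Independent naive WL oracle using nested-tuple labels."""

    def label(g, v, k):
        if k == 0:
            return labels_list[g][v]
        return (
            label(g, v, k - 1),
            tuple(sorted(label(g, u, k - 1) for u in adj_list[g][v])),
        )

    feats = []
    for g in range(len(labels_list)):
        c = Counter()
        for k in range(h + 1):
            for v in range(len(labels_list[g])):
                c[(k, label(g, v, k))] += 1
        feats.append(c)
    n = len(feats)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = sum(ci * feats[j].get(key, 0) for key, ci in feats[i].items())
    return K


class TestWLKernel:
    def test_path_vs_triangle_hand_refinement(self):
        """3-node path (low, high, low) vs triangle, h=1: iteration 0
        histograms agree (contribution 5); at iteration 1 only the
        centre labels (high, {low, low}) coincide, adding 1."""
        labels = [["low", "high", "low"], ["low", "high", "low"]]
        adj = [[[1], [0, 2], [1]], [[1, 2], [0, 2], [0, 1]]]
        K = _feature_gram(_wl_feature_maps(labels, adj, h=1))
        assert K[0, 1] == 6.0
        assert K[0, 0] == 10.0 and K[1, 1] == 10.0

    def test_h0_equals_label_histogram_kernel(self):
        graphs = random_graphs(6, seed=4)
        K = wl_kernel(graphs, h=0).values
        for i, gi in enumerate(graphs):
            hi = Counter(gi.states)
            for j, gj in enumerate(graphs):
                hj = Counter(gj.states)
                expected = sum(c * hj.get(s, 0) for s, c in hi.items())
                assert K[i, j] == pytest.approx(expected)

    def test_label_isomorphic_graphs_indistinguishable(self, stress_vector):
        g1 = build_deviation_graph(stress_vector, 0.1)
        g2 = build_deviation_graph(stress_vector, 0.1)
        K = wl_kernel([g1, g2], h=2).values
        assert K[0, 0] == pytest.approx(K[0, 1]) == pytest.approx(K[1, 1])

    @pytest.mark.parametrize("h", [0, 1, 2, 3])
    def test_matches_naive_recursive_oracle(self, h):
        graphs = random_graphs(4, seed=5)
        labels = [list(g.states) for g in graphs]
        from pgk.kernels import _graph_adjacency

        adj = [_graph_adjacency(g) for g in graphs]
        K = wl_kernel(graphs, h=h).values
        assert np.allclose(K, naive_wl_kernel(labels, adj, h))

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            wl_kernel(random_graphs(2), h=-1)

    def test_complete_graph_degenerates_to_histogram(self):
        """On unpruned complete graphs every neighbourhood multiset is
        determined by the global label histogram and the centre label,
        so graphs with equal histograms stay indistinguishable at any h."""
        v1 = PerceptualTraitVector(owner_id="a", intensities=np.array([0.1, 0.1, 0.5, 0.5, 0.9, 0.9]))
        v2 = PerceptualTraitVector(owner_id="b", intensities=np.array([0.9, 0.5, 0.1, 0.9, 0.5, 0.1]))
        g1, g2 = build_deviation_graph(v1, 0.0), build_deviation_graph(v2, 0.0)
        K = wl_kernel([g1, g2], h=3).values
        assert K[0, 1] == pytest.approx(K[0, 0])


class TestSPKernel:
    def test_path_graph_hand_floyd_warshall(self):
        """Path A-B-C with unit weights: distances {1, 1, 2}; the
        self-kernel is the sum of squared triple counts."""
        labels = ["low", "high", "low"]
        edges = [(0, 1, 1.0), (1, 2, 1.0)]
        feats = _sp_features(labels, edges, bin_width=0.1)
        assert feats == {(("high", "low"), 10): 2, (("low", "low"), 20): 1}
        K = _feature_gram([feats])
        assert K[0, 0] == 2**2 + 1**2

    def test_identical_graphs_maximal_after_normalisation(self, stress_vector):
        g = build_deviation_graph(stress_vector, 0.1)
        graphs = [g] + random_graphs(5, seed=6)
        K = sp_kernel(graphs, bin_width=0.1, normalised=True).values
        assert np.argmax(K[0]) in (0,) or K[0, 0] == pytest.approx(K[0].max())

    def test_totally_pruned_graph_has_zero_kernel(self, healthy_vector):
        flat = PerceptualTraitVector(owner_id="flat", intensities=np.full(6, 0.5))
        g_empty = build_deviation_graph(flat, 0.5)
        g = build_deviation_graph(healthy_vector, 0.1)
        K = sp_kernel([g_empty, g], bin_width=0.1).values
        assert K[0, 1] == 0.0 and K[0, 0] == 0.0

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            sp_kernel(random_graphs(2), bin_width=0.0)

    def test_unreachable_pairs_skipped(self):
        # two components: distances across them are absent from features
        labels = ["low", "low", "high"]
        edges = [(0, 1, 1.0)]
        feats = _sp_features(labels, edges, bin_width=1.0)
        assert feats == {(("low", "low"), 1): 1}


class TestCheckPsd:
    def test_identity_is_psd(self):
        lam, verdict = check_psd(np.eye(3))
        assert lam == pytest.approx(1.0) and verdict

    def test_indefinite_matrix_detected(self):
        lam, verdict = check_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert lam == pytest.approx(-1.0) and not verdict

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            check_psd(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError, match="square"):
            check_psd(np.zeros((2, 3)))

    def test_linear_gram_is_psd_by_construction(self):
        km = gram_matrix(random_graphs(30, seed=7), variant="linear")
        lam, verdict = check_psd(km)
        assert verdict


@pytest.fixture(scope="module")
def graphs():
    return random_graphs(40, seed=11)


class TestMercerProperties:
    """Symmetry, PSD and normalisation closure on random graph sets."""

    @pytest.mark.parametrize(
        "builder",
        [
            lambda gs: gram_matrix(gs, variant="rbf", sigma=0.5),
            lambda gs: gram_matrix(gs, variant="linear"),
            lambda gs: wl_kernel(gs, h=2),
            lambda gs: sp_kernel(gs, bin_width=0.1),
        ],
        ids=["pgk-rbf", "pgk-linear", "wl", "sp"],
    )
    def test_symmetric_and_psd(self, graphs, builder):
        km = builder(graphs)
        assert np.array_equal(km.values, km.values.T)
        assert km.smallest_eigenvalue >= -1e-8

    def test_normalised_kernel_unit_diagonal_and_psd(self, graphs):
        km = gram_matrix(graphs, variant="linear").normalised()
        d = np.diag(km.values)
        assert np.allclose(d[d > 0], 1.0)
        assert km.smallest_eigenvalue >= -1e-8

    def test_rbf_similarity_decreases_with_distance(self):
        base = np.zeros(15)
        sims = [
            pgk_pair(base, base + t, sigma=0.5)
            for t in np.linspace(0.0, 0.2, 6)[:, None] * np.ones(15)
        ]
        assert all(a > b for a, b in zip(sims, sims[1:]))
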