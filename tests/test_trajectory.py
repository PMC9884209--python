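"""Normalisation, CA, diffusion maps, clustering, pseudotime, Wasserstein."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from nephromorph import generate_latent_population
from nephromorph.trajectory import (
    backbone_pseudotime,
    bucket_fractions,
    ca_pearson_residuals,
    combine_distance_matrices,
    diffusion_map,
    fit_trajectory,
    louvain_clusters,
    rc_normalize,
    wasserstein_histogram_distance,
    wasserstein_patient_distances,
)


class TestRcNormalize:
    def test_example_row(self):
        out = rc_normalize(np.array([[1.0, 1.0, 2.0]]), scale=1e4, shift=False)
        np.testing.assert_allclose(out, [[2500.0, 2500.0, 5000.0]])

    def test_rows_sum_to_scale(self, rng):
        X = rng.uniform(0.1, 5, size=(30, 6))
        out = rc_normalize(X, scale=1e4)
        np.testing.assert_allclose(out.sum(axis=1), 1e4, rtol=1e-12)

    def test_homogeneity(self, rng):
        X = rng.uniform(0.1, 5, size=(10, 4))
        np.testing.assert_allclose(
            rc_normalize(X, shift=False), rc_normalize(10 * X, shift=False)
        )

    def test_negative_columns_are_shifted(self, rng):
        X = rng.normal(size=(20, 5))
        out = rc_normalize(X)
        assert np.isfinite(out).all()

    def test_zero_sum_row_errors(self):
        with pytest.raises(ValueError):
            rc_normalize(np.array([[0.0, 0.0], [1.0, 2.0]]), shift=False)


class TestCorrespondenceAnalysis:
    def test_rank_one_matrix_warns_degenerate(self):
        r = np.array([1.0, 2.0, 3.0])
        c = np.array([2.0, 5.0, 1.0, 4.0])
        with pytest.warns(UserWarning):
            emb, s = ca_pearson_residuals(np.outer(r, c), n_components=2)
        assert emb.shape[1] == 0

    def test_block_matrix_first_component_separates_groups(self, rng):
        from sklearn.metrics import silhouette_score

        A = rng.uniform(4, 6, size=(30, 3)) * [5, 1, 1]
        B = rng.uniform(4, 6, size=(30, 3)) * [1, 1, 5]
        M = np.vstack([A, B])
        emb, _ = ca_pearson_residuals(M, n_components=2)
        labels = np.r_[np.zeros(30), np.ones(30)]
        assert silhouette_score(emb[:, :1], labels) > 0.5

    def test_matches_independent_eigendecomposition(self):
        M = np.array(
            [
                [12.0, 4.0, 1.0, 7.0],
                [2.0, 9.0, 3.0, 1.0],
                [5.0, 5.0, 5.0, 5.0],
                [1.0, 2.0, 14.0, 3.0],
                [8.0, 1.0, 2.0, 2.0],
                [3.0, 7.0, 4.0, 9.0],
            ]
        )
        emb, s = ca_pearson_residuals(M, n_components=3)
        # oracle: eigendecomposition of S^T S gives V and singular values;
        # row coordinates are S V
        total = M.sum()
        E = M.sum(1, keepdims=True) @ M.sum(0, keepdims=True) / total
        S = (M - E) / np.sqrt(E)
        w, V = np.linalg.eigh(S.T @ S)
        order = np.argsort(-w)
        coords = S @ V[:, order[:3]]
        np.testing.assert_allclose(np.abs(emb), np.abs(coords), atol=1e-8)
        np.testing.assert_allclose(s, np.sqrt(w[order[:3]]), atol=1e-8)

    def test_rank_deficient_returns_fewer_components_with_warning(self, rng):
        M = rng.uniform(1, 2, size=(10, 3))
        with pytest.warns(UserWarning, match="fewer"):
            emb, _ = ca_pearson_residuals(M, n_components=5)
        assert emb.shape[1] <= 2


class TestDiffusionMap:
    def test_recovers_noisy_curve_parameter(self, rng):
        t = np.sort(rng.uniform(0, 1, 300))
        X = np.column_stack(
            [np.cos(2 * t), np.sin(2 * t), t**2]
        ) + rng.normal(0, 0.01, size=(300, 3))
        coords, _ = diffusion_map(X, n_components=2)
        rho = spearmanr(coords[:, 0], t).statistic
        assert abs(rho) >= 0.9

    def test_duplicated_dataset_same_per_point_values(self, rng):
        X = rng.normal(size=(60, 4))
        c1, _ = diffusion_map(X, n_components=3)
        c2, _ = diffusion_map(np.vstack([X, X]), n_components=3)
        np.testing.assert_allclose(np.vstack([c1, c1]), c2, atol=1e-6)

    def test_eigenvalues_sorted_by_magnitude(self, rng):
        X = rng.normal(size=(80, 5))
        _, lam = diffusion_map(X, n_components=6)
        mags = np.abs(lam)
        assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))

    def test_disconnected_knn_graph_is_reconnected(self, rng):
        A = rng.normal(0, 0.1, size=(40, 2))
        B = rng.normal(50, 0.1, size=(40, 2))
        with pytest.warns(UserWarning, match="reconnect"):
            coords, _ = diffusion_map(np.vstack([A, B]), n_components=2, k_nn=5)
        assert np.isfinite(coords).all()

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            diffusion_map(rng.normal(size=(4, 2)), n_components=4)


class TestLouvain:
    def test_two_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X = np.vstack(
            [rng.normal(0, 0.3, size=(150, 2)), rng.normal(5, 0.3, size=(150, 2))]
        )
        truth = np.r_[np.zeros(150), np.ones(150)]
        labels = louvain_clusters(X, k_nn=20, seed=0)
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_single_blob_stays_coarse(self, rng):
        labels = louvain_clusters(rng.normal(0, 0.1, size=(200, 2)), seed=0)
        assert len(set(labels)) < 5

    def test_same_seed_identical_partition(self, rng):
        X = rng.normal(size=(100, 2))
        a = louvain_clusters(X, seed=3)
        b = louvain_clusters(X, seed=3)
        assert (a == b).all()

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            louvain_clusters(rng.normal(size=(10, 2)), k_nn=20)


class TestBackbonePseudotime:
    def three_cluster_line(self):
        coords = np.array(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [5.1, 0.0], [10.0, 0.0], [10.1, 0.0]]
        )
        labels = np.array([0, 0, 1, 1, 2, 2])
        return coords, labels

    def test_endpoints_score_zero_and_hundred(self):
        coords, labels = self.three_cluster_line()
        pt = backbone_pseudotime(coords, labels, [0, 1, 2])
        assert pt.min() == 0.0 and pt.max() == 100.0
        assert pt[0] < pt[2] < pt[4]

    def test_reversed_backbone_mirrors_pseudotime(self):
        coords, labels = self.three_cluster_line()
        a = backbone_pseudotime(coords, labels, [0, 1, 2])
        b = backbone_pseudotime(coords, labels, [2, 1, 0])
        np.testing.assert_allclose(a, 100.0 - b, atol=1e-9)

    def test_off_backbone_instances_get_nan(self):
        coords, labels = self.three_cluster_line()
        pt = backbone_pseudotime(coords, labels, [0, 1])
        assert np.isnan(pt[labels == 2]).all()
        assert np.isfinite(pt[labels != 2]).all()

    def test_single_cluster_backbone_rejected(self):
        coords, labels = self.three_cluster_line()
        with pytest.raises(ValueError):
            backbone_pseudotime(coords, labels, [1])

    def test_latent_time_recovery_small(self, rng):
        t = rng.uniform(0, 1, 400)
        coords = np.column_stack([10 * t, np.zeros(400)]) + rng.normal(
            0, 0.2, size=(400, 2)
        )
        labels = np.clip((t * 4).astype(int), 0, 3)
        pt = backbone_pseudotime(coords, labels, [0, 1, 2, 3])
        assert abs(spearmanr(pt, t).statistic) >= 0.9


class TestBucketFractions:
    def test_single_condition_every_bucket_one(self, rng):
        pt = rng.uniform(0, 100, 500)
        table, _ = bucket_fractions(pt, np.repeat("only", 500))
        filled = table.dropna()
        assert (filled["only"] == 1.0).all()

    def test_fractions_sum_to_one_per_nonempty_bucket(self, rng):
        pt = rng.uniform(0, 100, 500)
        cond = rng.choice(["a", "b", "c"], 500)
        table, _ = bucket_fractions(pt, cond)
        sums = table.dropna().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_monotone_condition_probability_gives_monotone_curve(self, rng):
        t = rng.uniform(0, 1, 3000)
        cond = np.where(rng.uniform(size=3000) < t, "disease", "healthy")
        table, curves = bucket_fractions(t * 100, cond)
        smoothed = curves["disease"]
        # monotone up to one bucket's worth of wiggle
        diffs = np.diff(smoothed)
        assert (diffs >= -0.05).all()
        assert smoothed[-1] > smoothed[0]


class TestWasserstein:
    def test_identical_histograms_zero(self, rng):
        cent = rng.normal(size=(4, 2))
        cost = cdist(cent, cent)
        p = rng.dirichlet(np.ones(4))
        assert wasserstein_histogram_distance(p, p, cost) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_point_masses_give_ground_distance(self, rng):
        cent = rng.normal(size=(3, 2))
        cost = cdist(cent, cent)
        p = np.array([1.0, 0.0, 0.0])
        q = np.array([0.0, 1.0, 0.0])
        assert wasserstein_histogram_distance(p, q, cost) == pytest.approx(
            cost[0, 1], abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_unit_mass_matching_oracle(self, seed):
        """Histograms with masses k/6 reduce to a bipartite matching."""
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(seed)
        cent = rng.normal(size=(3, 2))
        cost = cdist(cent, cent)
        counts_p = rng.multinomial(6, [1 / 3] * 3)
        counts_q = rng.multinomial(6, [1 / 3] * 3)
        p, q = counts_p / 6.0, counts_q / 6.0
        # expand to six unit masses each and match them optimally
        src = np.repeat(np.arange(3), counts_p)
        dst = np.repeat(np.arange(3), counts_q)
        C = cost[np.ix_(src, dst)]
        ri, ci = linear_sum_assignment(C)
        oracle = C[ri, ci].sum() / 6.0
        assert wasserstein_histogram_distance(p, q, cost) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_metric_axioms_on_random_triples(self, rng):
        cent = rng.normal(size=(4, 2))
        cost = cdist(cent, cent)
        worst = 0.0
        for _ in range(50):
            a, b, c = rng.dirichlet(np.ones(4), 3)
            dab = wasserstein_histogram_distance(a, b, cost)
            dba = wasserstein_histogram_distance(b, a, cost)
            dbc = wasserstein_histogram_distance(b, c, cost)
            dac = wasserstein_histogram_distance(a, c, cost)
            worst = max(worst, abs(dab - dba), dac - (dab + dbc),
                        wasserstein_histogram_distance(a, a, cost))
        assert worst <= 1e-9

    def test_patient_distance_matrix_and_combination(self, rng):
        cent = rng.normal(size=(3, 2))
        lab = {
            "p1": np.array([0, 0, 1]),
            "p2": np.array([2, 2, 2]),
            "p3": np.array([0, 1, 2]),
        }
        D = wasserstein_patient_distances(lab, cent)
        assert (D.to_numpy().diagonal() == 0).all()
        assert D.loc["p1", "p2"] == pytest.approx(D.loc["p2", "p1"])
        comb = combine_distance_matrices(D, D * 2.0)
        np.testing.assert_allclose(comb.to_numpy(),
                                   (D / D.to_numpy().max()).to_numpy(),
                                   atol=1e-12)


class TestEndToEnd:
    def test_noiseless_population_first_component_monotone_in_t(self):
        X, t, cond = generate_latent_population(
            n_instances=300, noise_sd=0.0, seed=0
        )
        emb, _ = ca_pearson_residuals(rc_normalize(X), n_components=5)
        coords, _ = diffusion_map(emb, n_components=2)
        rho = spearmanr(coords[:, 0], t).statistic
        assert abs(rho) > 0.999

    def test_same_seed_bit_identical_result(self):
        X, t, cond = generate_latent_population(n_instances=400, seed=5)
        r1 = fit_trajectory(X, condition=cond,
                            severity_order=["healthy", "intermediate", "diseased"],
                            seed=11)
        r2 = fit_trajectory(X, condition=cond,
                            severity_order=["healthy", "intermediate", "diseased"],
                            seed=11)
        np.testing.assert_array_equal(r1.diffusion_coords, r2.diffusion_coords)
        np.testing.assert_array_equal(r1.cluster_labels, r2.cluster_labels)
        np.testing.assert_array_equal(r1.pseudotime, r2.pseudotime)
        assert r1.backbone == r2.backbone

    def test_pseudotime_spans_zero_to_hundred(self):
        X, t, cond = generate_latent_population(n_instances=600, seed=2)
        res = fit_trajectory(X, condition=cond,
                             severity_order=["healthy", "intermediate", "diseased"],
                             seed=2)
        ok = np.isfinite(res.pseudotime)
        assert res.pseudotime[ok].min() == 0.0
        assert res.pseudotime[ok].max() == 100.0
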