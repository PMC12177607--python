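"""Descriptor cleaning, correlation filtering, PCA, K-means and quality
indices, consensus k selection, representative selection."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from odorkit import synth
from odorkit.chemspace import (
    DescriptorMatrix, KMeansClusterer, centroid_distances, clean_descriptors,
    cluster_quality, correlation_filter, kmeans, pca, select_k,
    select_representatives,
)


def make_dm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    return DescriptorMatrix(ids=[f"m{i}" for i in range(values.shape[0])],
                            descriptor_names=names, values=values)


def exhaustive_two_means(X):
    """Exact k=2 optimum by enumerating every 2-partition (n <= 10)."""
    n = X.shape[0]
    best = np.inf
    for mask in range(1, 2 ** n - 1):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        w = 0.0
        for part in (X[sel], X[~sel]):
            w += ((part - part.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return best


class TestCleaning:
    def test_nonfinite_and_constant_dropped(self):
        vals = np.column_stack([
            np.arange(5.0), np.full(5, np.nan), np.full(5, 7.0), np.arange(5.0) ** 2])
        out = clean_descriptors(make_dm(vals))
        assert out.descriptor_names == ["d0", "d3"]

    def test_clean_matrix_unchanged(self):
        dm = make_dm(np.random.default_rng(0).normal(size=(6, 3)))
        out = clean_descriptors(dm)
        np.testing.assert_array_equal(out.values, dm.values)

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError):
            clean_descriptors(make_dm(np.ones((4, 2))))


class TestCorrelationFilter:
    def test_exact_copy_dropped(self):
        x = np.arange(10.0)
        dm = make_dm(np.column_stack([x, 2 * x]))
        out, dropped = correlation_filter(dm)
        assert dropped == ["d1"]
        assert out.descriptor_names == ["d0"]

    def test_threshold_boundary(self):
        # construct y = r*x + sqrt(1-r^2)*z with x, z exactly orthonormal
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        for r, expect_drop in ((0.96, True), (0.94, False)):
            y = r * x + np.sqrt(1 - r * r) * z
            _, dropped = correlation_filter(make_dm(np.column_stack([x, y])), 0.95)
            assert (dropped == ["d1"]) == expect_drop

    def test_threshold_above_one_keeps_all(self):
        x = np.arange(10.0)
        _, dropped = correlation_filter(make_dm(np.column_stack([x, 2 * x])), 1.0 + 1e-9)
        assert dropped == []

    def test_anticorrelation_counts(self):
        x = np.arange(10.0)
        _, dropped = correlation_filter(make_dm(np.column_stack([x, -3 * x])))
        assert dropped == ["d1"]


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        X = np.column_stack([x, 2 * x + rng.normal(scale=1e-4, size=300)])
        res = pca(X, m=1)
        assert res.explained_variance_ratio[0] >= 0.999

    def test_isotropic_variance_split(self):
        X = np.random.default_rng(42).normal(size=(5000, 2))
        res = pca(X, m=2)
        np.testing.assert_allclose(res.explained_variance_ratio, [0.5, 0.5], atol=0.03)

    def test_full_reconstruction(self):
        X = np.random.default_rng(3).normal(size=(30, 4))
        res = pca(X, m=4)
        Z = (X - res.means) / res.sds
        np.testing.assert_allclose(res.scores @ res.loadings.T, Z, atol=1e-8)

    def test_loadings_orthonormal_and_sign_fixed(self):
        res = pca(np.random.default_rng(4).normal(size=(50, 5)), m=3)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-8)
        for j in range(3):
            assert res.loadings[np.argmax(np.abs(res.loadings[:, j])), j] > 0

    def test_variance_target_selects_components(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(scale=s, size=400) for s in (10, 10, 0.1)])
        assert pca(X, m=0.6).m == 2  # z-scoring equalizes: 2 of 3 cover 2/3

    def test_m_exceeding_rank_is_error(self):
        with pytest.raises(ValueError):
            pca(np.random.default_rng(0).normal(size=(10, 3)), m=5)


class TestKMeans:
    def test_one_dimensional_example(self):
        km = kmeans(np.array([0.0, 1.0, 10.0, 11.0]), 2, seed=0)
        assert km.wcss == pytest.approx(1.0)
        assert sorted(km.centroids.ravel()) == [0.5, 10.5]

    def test_k_equals_n(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        assert kmeans(X, 6, seed=0).wcss == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        X = np.random.default_rng(1).normal(size=(40, 2))
        a = kmeans(X, 3, seed=5)
        b = kmeans(X + 100.0, 3, seed=5)
        assert a.wcss == pytest.approx(b.wcss, rel=1e-9)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        X = rng.normal(size=(n, 2))
        km = kmeans(X, 2, seed=seed, n_init=20)
        assert km.wcss == pytest.approx(exhaustive_two_means(X), rel=1e-9)

    def test_invalid_k(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            kmeans(X, 4)
        with pytest.raises(ValueError):
            kmeans(X, 0)

    def test_sklearn_estimator_protocol(self):
        est = KMeansClusterer(k=3, random_state=0)
        assert est.get_params()["k"] == 3
        X = np.random.default_rng(2).normal(size=(30, 2))
        labels = est.set_params(k=2).fit_predict(X)
        assert set(labels) == {0, 1}
        assert est.predict(X[:5]).shape == (5,)

    def test_wcss_cross_check_sklearn(self):
        from sklearn.cluster import KMeans as SKKMeans

        X = np.random.default_rng(6).normal(size=(120, 2))
        X[:60] += 6.0
        ours = kmeans(X, 2, seed=0).wcss
        theirs = SKKMeans(n_clusters=2, n_init=10, random_state=0).fit(X).inertia_
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestClusterQuality:
    @pytest.fixture
    def toy(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        return X, kmeans(X, 2, seed=0)

    def test_hand_computed_indices(self, toy):
        X, km = toy
        q = cluster_quality(X, km)
        assert q.wcss == pytest.approx(1.0)
        assert q.silhouette_values[0] == pytest.approx((10.5 - 1) / 10.5, abs=1e-6)
        assert q.davies_bouldin == pytest.approx(0.1, abs=1e-6)
        assert q.calinski_harabasz == pytest.approx(200.0, abs=1e-6)

    def test_aic_bic_difference(self, toy):
        X, km = toy
        q = cluster_quality(X, km)
        assert q.n_parameters == 3  # k*m + 1
        assert q.aic - q.bic == pytest.approx(3 * (2 - np.log(4)), abs=1e-9)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_bic_aic_identity_random(self, k):
        X = np.random.default_rng(k).normal(size=(40, 3))
        q = cluster_quality(X, kmeans(X, k, seed=1))
        assert q.bic - q.aic == pytest.approx(q.n_parameters * (np.log(40) - 2), abs=1e-9)

    def test_indices_match_sklearn(self):
        from sklearn.metrics import (
            calinski_harabasz_score, davies_bouldin_score, silhouette_score)

        X = np.random.default_rng(9).normal(size=(80, 3))
        X[:40] += 3.0
        km = kmeans(X, 3, seed=2)
        q = cluster_quality(X, km)
        assert q.silhouette == pytest.approx(silhouette_score(X, km.labels), abs=1e-6)
        assert q.davies_bouldin == pytest.approx(davies_bouldin_score(X, km.labels), abs=1e-6)
        assert q.calinski_harabasz == pytest.approx(
            calinski_harabasz_score(X, km.labels), abs=1e-6)

    def test_singleton_silhouette_zero_and_flagged(self):
        X = np.array([[0.0], [0.1], [50.0]])
        km = kmeans(X, 2, seed=0)
        q = cluster_quality(X, km)
        assert q.singleton_clusters
        lone = int(np.argmax(X.ravel() == 50.0))
        assert q.silhouette_values[lone] == 0.0

    def test_separation_limit_silhouette_to_one(self):
        X = np.array([[0.0], [0.001], [1e6], [1e6 + 0.001]])
        q = cluster_quality(X, kmeans(X, 2, seed=0))
        assert q.silhouette > 0.999


class TestSelectK:
    def test_well_separated_blobs_recover_k(self):
        dm, _ = synth.gen_mixture(synth.MixtureSpec(seed=0))
        res = select_k(pca(dm, m=2).scores, range(2, 11), seed=0)
        assert res.chosen_k == 5
        assert not res.weak_structure

    def test_single_blob_flags_weak_structure(self):
        X = np.random.default_rng(0).normal(size=(80, 8))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            res = select_k(X, range(2, 7), seed=0)
        assert res.weak_structure
        assert (res.table["silhouette"] < 0.3).all()
        # WCSS must still be monotone decreasing in k (no elbow assertion)
        assert res.table["wcss"].is_monotonic_decreasing

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(1).normal(size=(60, 2))
        X[:30] += 5
        a = select_k(X, range(2, 6), seed=3)
        b = select_k(X, range(2, 6), seed=3)
        assert a.chosen_k == b.chosen_k
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_range(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            select_k(X, [])
        with pytest.raises(ValueError):
            select_k(X, range(2, 50))


class TestRepresentatives:
    def test_point_distances(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        km = kmeans(X, 1, seed=0)
        km.centroids[:] = 0.0
        km.labels[:] = 0
        d = centroid_distances(X, km)
        np.testing.assert_allclose(d, [0.0, 5.0])

    def test_matches_brute_force(self):
        X = np.random.default_rng(2).normal(size=(50, 3))
        km = kmeans(X, 4, seed=1)
        d = centroid_distances(X, km)
        brute = [np.sqrt(((X[i] - km.centroids[km.labels[i]]) ** 2).sum())
                 for i in range(50)]
        np.testing.assert_allclose(d, brute, atol=1e-12)

    def test_five_clusters_four_each(self):
        dm, _ = synth.gen_mixture(synth.MixtureSpec(seed=1))
        scores = pca(dm, m=2).scores
        km = kmeans(scores, 5, seed=1)
        reps = select_representatives(km, centroid_distances(scores, km), 4, ids=dm.ids)
        assert reps.total == 20
        assert not reps.truncated_clusters
        for members in reps.per_cluster.values():
            dists = [d for _, d in members]
            assert dists == sorted(dists)

    def test_small_cluster_truncated(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1], [10.2], [10.3]])
        km = kmeans(X, 2, seed=0)
        reps = select_representatives(km, centroid_distances(X, km), 4)
        assert reps.total == 6
        assert len(reps.truncated_clusters) == 1

    def test_whole_cluster_in_distance_order(self):
        X = np.array([[0.0], [0.5], [0.2]])
        km = kmeans(X, 1, seed=0)
        reps = select_representatives(km, centroid_distances(X, km), 3,
                                      ids=["a", "b", "c"])
        assert [n for n, _ in reps.per_cluster[0]] == ["c", "a", "b"]

    def test_invalid_m(self):
        X = np.zeros((4, 1))
        km = kmeans(X, 1, seed=0)
        with pytest.raises(ValueError):
            select_representatives(km, centroid_distances(X, km), 0)

    def test_row_permutation_stability(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        X[:20] += 8
        km = kmeans(X, 2, seed=0)
        d = centroid_distances(X, km)
        reps = select_representatives(km, d, 3, ids=[f"m{i}" for i in range(40)])
        perm = rng.permutation(40)
        km2 = kmeans(X[perm], 2, seed=0)
        d2 = centroid_distances(X[perm], km2)
        reps2 = select_representatives(km2, d2, 3, ids=[f"m{i}" for i in perm])
        chosen = {frozenset(n for n, _ in v) for v in reps.per_cluster.values()}
        chosen2 = {frozenset(n for n, _ in v) for v in reps2.per_cluster.values()}
        assert chosen == chosen2
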