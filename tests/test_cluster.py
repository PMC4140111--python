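import numpy as np
import pytest

from plsca_elman.cluster import (
    cut_tree,
    inverse_covariance,
    mahalanobis,
    pairwise_mahalanobis,
    partition_summarize,
    pooled_covariance,
    upgma_linkage,
)


def naive_upgma(D):
    """O(n^3) oracle: recompute every cross-pair squared average from the
    ORIGINAL distances at each step."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                sq = np.mean([D[x, y] ** 2 for x in clusters[a] for y in clusters[b]])
                if best is None or sq < best[0] - 1e-15 * max(abs(best[0]), 1.0):
                    best = (sq, a, b)
        sq, a, b = best
        merges.append((a, b, np.sqrt(sq), len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestPooledCovariance:
    def test_two_point_hand_value(self):
        V = pooled_covariance(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(V, [[2.0, 2.0], [2.0, 2.0]])

    def test_large_sample_identity(self):
        X = np.random.default_rng(1).normal(size=(5000, 3))
        np.testing.assert_allclose(pooled_covariance(X), np.eye(3), atol=0.1)

    def test_rank_deficiency_detected(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        V = pooled_covariance(X)
        assert np.linalg.matrix_rank(V) == 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pooled_covariance(np.ones((1, 3)))


class TestMahalanobis:
    def test_identity_reduces_to_euclidean(self):
        assert mahalanobis([0, 0], [3, 4], np.eye(2)) == pytest.approx(5.0)

    def test_self_distance_zero(self, rng):
        x = rng.normal(size=5)
        assert mahalanobis(x, x, np.eye(5)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_affine_invariance(self, seed):
        # distances are unchanged by any invertible linear map when the
        # covariance is recomputed from the transformed data
        g = np.random.default_rng(seed)
        X = g.normal(size=(20, 4))
        A = g.normal(size=(4, 4)) + 4 * np.eye(4)
        D1 = pairwise_mahalanobis(X, np.linalg.inv(pooled_covariance(X)))
        XA = X @ A
        D2 = pairwise_mahalanobis(XA, np.linalg.inv(pooled_covariance(XA)))
        np.testing.assert_allclose(D1, D2, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mahalanobis([1, 2, 3], [1, 2], np.eye(2))


class TestUpgma:
    def test_three_point_hand_example(self):
        # after merging (A,B) at 1, distance to C is the cross-pair squared
        # average sqrt((4^2+5^2)/2)
        D = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = upgma_linkage(D)
        (a, b, h1, s1), (c, d, h2, s2) = tree.merges
        assert (a, b, s1) == (0, 1, 2)
        assert h1 == pytest.approx(1.0)
        assert h2 == pytest.approx(np.sqrt((16 + 25) / 2))

    def test_equidistant_heights(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = upgma_linkage(D)
        np.testing.assert_allclose(tree.heights, 1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_oracle(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(4, 13))
        M = g.uniform(0.1, 10, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = upgma_linkage(D).merges
        ref = naive_upgma(D)
        for (a1, b1, h1, s1), (a2, b2, h2, s2) in zip(ours, ref):
            assert {a1, b1} == {a2, b2}
            assert s1 == s2
            assert h1 == pytest.approx(h2, abs=1e-10)

    def test_heights_monotone(self, rng):
        for _ in range(10):
            M = rng.uniform(0, 5, size=(10, 10))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            h = upgma_linkage(D).heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_scipy_cross_check(self, rng):
        # independent oracle: scipy average linkage on squared distances
        # equals our squared heights and induces the same partitions
        hierarchy = pytest.importorskip("scipy.cluster.hierarchy")
        squareform = pytest.importorskip("scipy.spatial.distance").squareform
        M = rng.uniform(0.5, 8, size=(15, 15))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = upgma_linkage(D)
        Z = hierarchy.linkage(squareform(D**2), method="average")
        np.testing.assert_allclose(tree.heights**2, Z[:, 2], atol=1e-8)
        for k in (2, 3, 5):
            ours = cut_tree(tree, k=k)
            ref = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            from conftest import rand_index

            assert rand_index(ours, ref) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            upgma_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            upgma_linkage(-np.ones((3, 3)) + np.eye(3))  # negative


class TestCutTree:
    def _tree(self, rng, n=10):
        M = rng.uniform(0, 5, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        return upgma_linkage(D)

    def test_extreme_cuts(self, rng):
        tree = self._tree(rng)
        assert len(np.unique(cut_tree(tree, k=tree.leaf_count))) == tree.leaf_count
        assert len(np.unique(cut_tree(tree, k=1))) == 1

    @pytest.mark.parametrize("k", [2, 3, 4, 7])
    def test_k_rule_produces_k_subclasses(self, rng, k):
        labels = cut_tree(self._tree(rng), k=k)
        assert len(np.unique(labels)) == k
        assert labels.min() == 1  # first-appearance labeling

    def test_lambda_and_k_rules_agree_between_heights(self, rng):
        tree = self._tree(rng)
        h = tree.heights
        k = 4
        lam = (h[-(k)] + h[-(k - 1)]) / 2  # strictly between merge heights
        np.testing.assert_array_equal(cut_tree(tree, lam=lam), cut_tree(tree, k=k))

    def test_blob_recovery(self, blobs3):
        from conftest import rand_index

        X, truth = blobs3
        D = pairwise_mahalanobis(X, np.linalg.inv(pooled_covariance(X)))
        labels = cut_tree(upgma_linkage(D), k=3)
        assert rand_index(labels, truth) == 1.0

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            cut_tree(self._tree(rng), k=0)


class TestPartitionSummarize:
    def test_centers_are_means(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0]])
        part = partition_summarize(X, np.array([1, 1, 2]))
        np.testing.assert_allclose(part.centers[0], [1.0, 1.0])
        np.testing.assert_allclose(part.centers[1], [5.0, 5.0])  # singleton

    def test_empty_subclass_rejected(self):
        with pytest.raises(ValueError):
            partition_summarize(np.eye(3), np.array([1, 1, 3]))

    def test_rank_deficient_pinv_close_to_ridge(self, rng):
        Z = rng.normal(size=(20, 2))
        X = Z @ rng.normal(size=(2, 5))  # rank 2 in 5-d
        part = partition_summarize(X, np.ones(20, dtype=int))
        D = pairwise_mahalanobis(X, part.pooled_inverse_covariance)
        assert np.isfinite(D).all()
        V = pooled_covariance(X)
        ridge = inverse_covariance(V, method="ridge")
        D2 = pairwise_mahalanobis(X, ridge)
        np.testing.assert_allclose(D, D2, atol=1e-2)
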