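import numpy as np
import pytest

from smrt import (
    ValidationError,
    cluster_single,
    connectivity_from_labels,
    perturb,
    perturbed_connectivity,
    stability_score,
)
from smrt.reduction import ReducedMatrix


def check_connectivity_invariants(C):
    assert np.array_equal(C, C.T)
    np.testing.assert_allclose(np.diag(C), 1.0)
    assert C.min() >= 0 and C.max() <= 1


class TestPerturb:
    def test_zero_noise_is_identity(self, rng):
        X = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(perturb(X, 0.0, rng), X)

    def test_negative_noise_rejected(self, rng):
        with pytest.raises(ValidationError):
            perturb(np.ones((2, 2)), -1.0, rng)

    def test_noise_is_zero_mean_with_correct_sd(self, rng):
        # Monte-Carlo over 10,000 replicates of a 2x2 matrix
        X = np.array([[1.0, -2.0], [0.5, 3.0]])
        sd = 0.7
        draws = np.stack([perturb(X, sd, rng) for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), X, atol=0.05)
        resid_sd = (draws - X).std()
        assert abs(resid_sd - sd) / sd < 0.02


class TestConnectivityFromLabels:
    def test_mixed_labels(self):
        np.testing.assert_array_equal(
            connectivity_from_labels([1, 1, 2]),
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
        )

    def test_uniform_labels_all_ones(self):
        np.testing.assert_array_equal(connectivity_from_labels([5, 5, 5]), np.ones((3, 3)))

    def test_distinct_labels_identity(self):
        np.testing.assert_array_equal(connectivity_from_labels([1, 2, 3]), np.eye(3))


class TestPerturbedConnectivity:
    def test_separated_clouds_give_block_structure(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.01, size=(10, 2)), rng.normal(100, 0.01, size=(10, 2))]
        )
        C = perturbed_connectivity(X, k=2, n_perturb=20, noise_sd=1.0, seed=0)
        check_connectivity_invariants(C)
        np.testing.assert_array_equal(C[:10, :10], 1.0)
        np.testing.assert_array_equal(C[10:, 10:], 1.0)
        np.testing.assert_array_equal(C[:10, 10:], 0.0)

    def test_single_replicate_is_binary(self, rng):
        X = rng.standard_normal((12, 3))
        C = perturbed_connectivity(X, k=3, n_perturb=1, noise_sd=0.1, seed=1)
        assert set(np.unique(C)) <= {0.0, 1.0}

    def test_duplicated_samples_stay_together(self, rng):
        X = rng.standard_normal((8, 2)) * 10
        X[3] = X[4]  # exact duplicates can never be separated by k-means
        C = perturbed_connectivity(X, k=2, n_perturb=15, noise_sd=1e-9, seed=2)
        assert C[3, 4] == 1.0

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            perturbed_connectivity(rng.standard_normal((4, 2)), k=5, n_perturb=1,
                                   noise_sd=1.0, seed=0)


class TestStabilityScore:
    def test_identical_matrices_score_one(self, rng):
        C = connectivity_from_labels(rng.integers(0, 3, size=10))
        assert stability_score(C, C) == 1.0

    def test_half_discrepancy_scores_half(self):
        orig = connectivity_from_labels([1, 1, 2, 2])
        pert = np.full((4, 4), 0.5)
        np.fill_diagonal(pert, 1.0)
        assert stability_score(orig, pert) == pytest.approx(0.5)

    def test_matches_naive_double_loop(self, rng):
        n = 15
        a = rng.uniform(size=(n, n))
        a = (a + a.T) / 2
        b = rng.uniform(size=(n, n))
        b = (b + b.T) / 2
        expected = 1.0 - np.mean(
            [abs(a[i, j] - b[i, j]) for i in range(n) for j in range(n) if i != j]
        )
        assert stability_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = rng.uniform(size=(6, 6))
        b = rng.uniform(size=(6, 6))
        assert stability_score(a, b) == pytest.approx(stability_score(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            stability_score(np.ones((3, 3)), np.ones((4, 4)))


class TestClusterSingle:
    def test_recovers_three_blobs(self, blob_layer):
        layer, truth = blob_layer
        reduced = ReducedMatrix(layer.sample_ids, layer.values)
        res = cluster_single(reduced, k_min=2, k_max=6, n_perturb=30, seed=0)
        assert res.k == 3
        from smrt import agreement

        assert agreement(res.labels, truth) == 1.0
        check_connectivity_invariants(res.connectivity.values)
        assert set(res.per_k_stability) == {2, 3, 4, 5, 6}

    def test_two_blobs_highly_stable(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(12, 1, (30, 4))])
        reduced = ReducedMatrix([f"S{i}" for i in range(60)], X)
        # perturb at the within-blob noise scale (separation is 12x that)
        res = cluster_single(reduced, k_min=2, k_max=5, n_perturb=30, noise_sd=1.0, seed=0)
        assert res.k == 2
        assert res.stability >= 0.99

    def test_fixed_seed_reproducible(self, rng):
        X = rng.standard_normal((30, 3))
        reduced = ReducedMatrix([f"S{i}" for i in range(30)], X)
        r1 = cluster_single(reduced, k_max=4, n_perturb=10, seed=9)
        r2 = cluster_single(reduced, k_max=4, n_perturb=10, seed=9)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.per_k_stability == r2.per_k_stability

    def test_labels_consecutive_from_one(self, blob_layer):
        layer, _ = blob_layer
        res = cluster_single(ReducedMatrix(layer.sample_ids, layer.values),
                             k_max=5, n_perturb=10, seed=0)
        assert sorted(set(res.labels)) == list(range(1, res.k + 1))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            cluster_single(ReducedMatrix(["a", "b"], np.ones((2, 2))))

    def test_degenerate_zero_variance_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValidationError, match="variance"):
            cluster_single(ReducedMatrix([f"S{i}" for i in range(10)], X))
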