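import numpy as np
import pytest

from smrt import (
    ValidationError,
    align_layers,
    knn_probabilities,
    propagate_multiomics,
    select_k,
    split_samples,
)
from smrt.propagate import ClassProbabilities
from smrt.reduction import ReducedMatrix

from conftest import make_layer


def reduced(ids, X):
    return ReducedMatrix(sample_ids=list(ids), scores=np.asarray(X, float))


def brute_force_knn(ref, labels, classes, query, k):
    """Naive all-pairs distance sort with ties broken by reference order."""
    probs = np.zeros((len(query), len(classes)))
    for qi, q in enumerate(query):
        d = [(float(np.sum((q - r) ** 2)), i) for i, r in enumerate(ref)]
        d.sort()  # lexicographic: distance, then reference index
        neigh = [labels[i] for _, i in d[:k]]
        for ci, c in enumerate(classes):
            probs[qi, ci] = sum(1 for lab in neigh if lab == c) / k
    return probs


class TestSplitSamples:
    def test_small_common_set_used_whole(self, rng):
        ids = [f"S{i:03d}" for i in range(100)]
        ds = align_layers([make_layer("a", ids, rng.normal(size=(100, 3)))])
        split = split_samples(ds, max_sampled=2000, seed=0)
        assert split.sampled_ids == sorted(ids)
        assert split.propagated_ids == []

    def test_large_common_set_subsampled_deterministically(self, rng):
        ids = [f"S{i:04d}" for i in range(5000)]
        ds = align_layers([make_layer("a", ids, rng.normal(size=(5000, 2)))])
        s1 = split_samples(ds, max_sampled=2000, seed=3)
        s2 = split_samples(ds, max_sampled=2000, seed=3)
        assert len(s1.sampled_ids) == 2000
        assert s1.sampled_ids == s2.sampled_ids
        assert set(s1.sampled_ids) | set(s1.propagated_ids) == set(ids)

    def test_sampled_restricted_to_common_samples(self, rng):
        a = make_layer("a", ["A", "B", "C"], rng.normal(size=(3, 2)))
        b = make_layer("b", ["B", "C"], rng.normal(size=(2, 2)))
        split = split_samples(align_layers([a, b]), max_sampled=2000, seed=0)
        assert set(split.sampled_ids) == {"B", "C"}
        assert split.propagated_ids == ["A"]


class TestSelectK:
    def test_perfect_separation_ties_break_to_smallest(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(50, 0.1, (40, 2))])
        y = np.repeat([1, 2], 40)
        k = select_k(reduced(range(80), X), y, k_grid=range(5, 21), folds=5, seed=0)
        assert k == 5

    def test_matches_brute_force_cv_error_table(self, rng):
        # mildly noisy two-class data where the CV error varies with k
        X = np.vstack([rng.normal(0, 1.5, (30, 2)), rng.normal(2.0, 1.5, (30, 2))])
        y = np.repeat([1, 2], 30)
        n, folds, seed = 60, 4, 11
        grid = list(range(1, 16))

        # reproduce the documented fold assignment, then compute errors naively
        fold_rng = np.random.default_rng(seed)
        fold_of = np.repeat(
            np.arange(folds), np.diff(np.linspace(0, n, folds + 1).astype(int))
        )
        fold_of = fold_of[fold_rng.permutation(n)]
        classes = np.array([1, 2])
        errors = []
        for k in grid:
            errs = []
            for f in range(folds):
                tr, te = fold_of != f, fold_of == f
                probs = brute_force_knn(X[tr], y[tr], classes, X[te], k)
                pred = classes[probs.argmax(axis=1)]
                errs.append((pred != y[te]).mean())
            errors.append(np.mean(errs))
        expected = grid[int(np.argmin(errors))]
        assert select_k(reduced(range(n), X), y, k_grid=grid, folds=folds, seed=seed) == expected

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(1, 3, size=40)
        while np.unique(y, return_counts=True)[1].min() < 2:
            y = rng.integers(1, 3, size=40)
        ks = {select_k(reduced(range(40), X), y, folds=4, seed=5) for _ in range(3)}
        assert len(ks) == 1

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] * 9 + [2])
        with pytest.raises(ValidationError):
            select_k(reduced(range(10), X), y)


class TestKnnProbabilities:
    def test_vote_fractions(self):
        ref = reduced(["a", "b", "c"], [[0.0], [1.0], [2.0]])
        q = reduced(["q"], [[0.6]])
        out = knn_probabilities(ref, [1, 1, 2], q, k=3)
        np.testing.assert_allclose(out.probabilities, [[2 / 3, 1 / 3]])

    def test_k1_is_one_hot(self):
        ref = reduced(["a", "b"], [[0.0], [5.0]])
        q = reduced(["q1", "q2"], [[0.4], [4.8]])
        out = knn_probabilities(ref, [1, 2], q, k=1)
        np.testing.assert_array_equal(out.probabilities, [[1, 0], [0, 1]])

    def test_matches_brute_force_oracle(self, rng):
        ref_X = rng.normal(size=(200, 4))
        labels = rng.integers(1, 3, size=200)
        query_X = rng.normal(size=(50, 4))
        out = knn_probabilities(
            reduced(range(200), ref_X), labels, reduced(range(50), query_X), k=7
        )
        expected = brute_force_knn(ref_X, labels, np.unique(labels), query_X, 7)
        np.testing.assert_array_equal(out.probabilities, expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            knn_probabilities(reduced([], np.empty((0, 2))), [], reduced(["q"], [[1, 1]]), k=1)


class TestPropagateMultiomics:
    def test_single_table_argmax(self):
        p = ClassProbabilities(["q"], np.array([1, 2]), np.array([[0.3, 0.7]]))
        assert propagate_multiomics([p]) == {"q": 2}

    def test_average_across_types(self):
        p1 = ClassProbabilities(["q"], np.array([1, 2]), np.array([[1.0, 0.0]]))
        p2 = ClassProbabilities(["q"], np.array([1, 2]), np.array([[0.2, 0.8]]))
        assert propagate_multiomics([p1, p2]) == {"q": 1}  # mean (0.6, 0.4)

    def test_query_in_one_layer_only(self):
        p1 = ClassProbabilities(["q1", "q2"], np.array([1, 2]),
                                np.array([[0.9, 0.1], [0.1, 0.9]]))
        p2 = ClassProbabilities(["q1"], np.array([1, 2]), np.array([[0.0, 1.0]]))
        out = propagate_multiomics([p1, p2])
        assert out["q2"] == 2  # layer 1 alone decides
        assert out["q1"] == 2  # mean (0.45, 0.55)

    def test_tie_goes_to_lowest_class(self):
        p = ClassProbabilities(["q"], np.array([1, 2]), np.array([[0.5, 0.5]]))
        assert propagate_multiomics([p]) == {"q": 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            propagate_multiomics([])
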