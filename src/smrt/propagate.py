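"""Big-cohort path: subsample, classify, propagate.

Perturbation clustering needs an n x n connectivity matrix, so for cohorts
beyond a threshold (default 2,000) only a *sampled* set — drawn from the
patients present in every layer — is clustered directly.  Every remaining
(*propagated*) patient is then assigned a subtype by k-nearest-neighbor vote
counting in the sampled set's component space, one kNN model per data type,
with the per-type subtype probabilities averaged and the argmax taken.  The
neighborhood size k is chosen per layer by cross-validated classification
error on the sampled set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import MultiOmicsDataset, ValidationError
from .reduction import ReducedMatrix

__all__ = [
    "SampleSplit",
    "ClassProbabilities",
    "split_samples",
    "select_k",
    "knn_probabilities",
    "propagate_multiomics",
]


@dataclass
class SampleSplit:
    """Partition of the cohort into directly clustered and propagated ids."""

    sampled_ids: list[str]
    propagated_ids: list[str]
    max_sampled: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.sampled_ids) & set(self.propagated_ids):
            raise ValidationError("sampled and propagated sets overlap")
        if len(self.sampled_ids) > self.max_sampled:
            raise ValidationError("sampled set exceeds max_sampled")


@dataclass
class ClassProbabilities:
    """Per-query subtype membership probabilities (rows sum to 1)."""

    sample_ids: list[str]
    classes: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.sample_ids), len(self.classes)):
            raise ValidationError("probability matrix shape mismatch")
        if p.min() < 0 or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("rows must be non-negative and sum to 1")
        self.probabilities = p


def split_samples(
    dataset: MultiOmicsDataset, max_sampled: int = 2000, seed: int = 0
) -> SampleSplit:
    """Choose the sampled set from the patients present in all layers.

    If the common set fits under ``max_sampled`` it is used whole; otherwise
    a seeded uniform subset without replacement is drawn.  Everything else
    in the union goes to the propagated set.
    """
    if max_sampled < 2:
        raise ValidationError("max_sampled must be >= 2")
    common = dataset.common_samples
    if not common:
        raise ValidationError("no sample is present in every layer")
    if len(common) <= max_sampled:
        sampled = list(common)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(common), size=max_sampled, replace=False)
        sampled = sorted(common[i] for i in idx)
    sampled_set = set(sampled)
    propagated = [s for s in dataset.all_samples if s not in sampled_set]
    return SampleSplit(
        sampled_ids=sampled, propagated_ids=propagated, max_sampled=max_sampled, seed=seed
    )


def _knn_vote_matrix(
    ref_scores: np.ndarray,
    ref_labels: np.ndarray,
    classes: np.ndarray,
    query_scores: np.ndarray,
    k: int,
    block_size: int = 2048,
) -> np.ndarray:
    """Vote fractions over ``classes`` for each query row.

    Exact search: full Euclidean distances, stable sort so equidistant
    references resolve by reference order.  Queries are processed in blocks
    to bound memory on large propagated sets.
    """
    n_ref = ref_scores.shape[0]
    votes = np.empty((query_scores.shape[0], classes.size))
    ref_sq = (ref_scores**2).sum(axis=1)
    class_index = {c: j for j, c in enumerate(classes)}
    idx_labels = np.array([class_index[c] for c in ref_labels])
    for start in range(0, query_scores.shape[0], block_size):
        q = query_scores[start : start + block_size]
        d2 = (q**2).sum(axis=1)[:, None] - 2 * q @ ref_scores.T + ref_sq[None, :]
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        neigh = idx_labels[order]  # block x k class indices
        counts = np.zeros((q.shape[0], classes.size))
        for j in range(classes.size):
            counts[:, j] = (neigh == j).sum(axis=1)
        votes[start : start + len(q)] = counts / k
    del n_ref
    return votes


def knn_probabilities(
    ref_scores: ReducedMatrix,
    ref_labels: Sequence[int],
    query_scores: ReducedMatrix,
    k: int,
) -> ClassProbabilities:
    """Subtype probabilities for each query: fraction of its k nearest
    references (Euclidean, reduced space) carrying each label."""
    ref = np.asarray(ref_scores.scores, dtype=float)
    labels = np.asarray(ref_labels)
    if ref.shape[0] == 0:
        raise ValidationError("empty reference set")
    if labels.shape != (ref.shape[0],):
        raise ValidationError("one reference label per reference sample required")
    if not 1 <= k <= ref.shape[0]:
        raise ValidationError(f"k={k} must be in [1, {ref.shape[0]}]")
    classes = np.unique(labels)
    probs = _knn_vote_matrix(ref, labels, classes, np.asarray(query_scores.scores), k)
    return ClassProbabilities(
        sample_ids=list(query_scores.sample_ids), classes=classes, probabilities=probs
    )


def select_k(
    scores: ReducedMatrix,
    labels: Sequence[int],
    k_grid: Sequence[int] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Cross-validated neighborhood size for kNN propagation.

    Samples are split into ``folds`` random (unstratified) folds; for every
    k in the grid (default 5..50, truncated to the training-fold size minus
    one) the mean held-out misclassification rate is computed, and the k
    with the lowest error wins, smallest k on ties.
    """
    X = np.asarray(scores.scores, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 members")
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(folds), np.diff(np.linspace(0, n, folds + 1).astype(int)))
    fold_of = fold_of[rng.permutation(n)]

    min_train = min(int((fold_of != f).sum()) for f in range(folds))
    if k_grid is None:
        k_grid = range(5, 51)
    grid = sorted({k for k in k_grid if 1 <= k <= min_train - 1})
    if not grid:
        grid = [min(5, min_train - 1)]

    errors = np.zeros(len(grid))
    for f in range(folds):
        train = fold_of != f
        test = ~train
        if test.sum() == 0:
            continue
        classes = np.unique(y[train])
        for gi, k in enumerate(grid):
            votes = _knn_vote_matrix(X[train], y[train], classes, X[test], k)
            pred = classes[votes.argmax(axis=1)]
            errors[gi] += (pred != y[test]).mean()
    errors /= folds
    return int(grid[int(errors.argmin())])


def propagate_multiomics(per_type_probs: Sequence[ClassProbabilities]) -> dict[str, int]:
    """Final subtype per query: average membership probabilities over the
    data types in which the query appears, then argmax (lowest class index
    on ties)."""
    if not per_type_probs:
        raise ValidationError("need at least one probability table")
    classes = np.unique(np.concatenate([p.classes for p in per_type_probs]))
    class_pos = {c: j for j, c in enumerate(classes)}

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    order: list[str] = []
    for table in per_type_probs:
        cols = np.array([class_pos[c] for c in table.classes])
        for i, sid in enumerate(table.sample_ids):
            if sid not in sums:
                sums[sid] = np.zeros(classes.size)
                counts[sid] = 0
                order.append(sid)
            sums[sid][cols] += table.probabilities[i]
            counts[sid] += 1
    return {
        sid: int(classes[int((sums[sid] / counts[sid]).argmax())]) for sid in order
    }
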