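"""Multi-omics integration of per-type connectivity matrices.

The per-layer perturbed connectivity matrices are averaged entrywise into a
single patient-similarity matrix S.  Candidate final partitions are drawn
from three similarity-based clusterers on the distance 1 - S — average-
linkage hierarchical cuts, partitioning around medoids, and an adaptive
("dynamic") cut of the hierarchical dendrogram — and the candidate whose
labels agree best (mean adjusted Rand index) with the individual data-type
partitions is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .core_io import ValidationError
from .perturb_cluster import ConnectivityMatrix

__all__ = [
    "SimilarityMatrix",
    "EnsembleCandidate",
    "merge_connectivities",
    "agreement",
    "candidate_partitions",
    "ensemble_select",
]

# tie-break order among algorithms when agreement and k are equal
_ALGO_RANK = {"hierarchical": 0, "medoid": 1, "dynamic-tree-cut": 2}

SimilarityMatrix = ConnectivityMatrix  # same invariants, different provenance


@dataclass
class EnsembleCandidate:
    algorithm: str
    labels: np.ndarray
    k: int
    agreement: float = float("nan")


def merge_connectivities(conns: Sequence[ConnectivityMatrix]) -> SimilarityMatrix:
    """Entrywise unweighted mean of per-type connectivity matrices."""
    if not conns:
        raise ValidationError("need at least one connectivity matrix")
    ids = conns[0].sample_ids
    for c in conns[1:]:
        if c.sample_ids != ids:
            raise ValidationError("connectivity matrices cover different sample sets")
    mean = np.mean([c.values for c in conns], axis=0)
    mean = (mean + mean.T) / 2  # guard against float summation asymmetry
    np.fill_diagonal(mean, 1.0)
    return SimilarityMatrix(sample_ids=list(ids), values=mean)


def agreement(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted Rand index between two partitions of the same samples."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError(f"label length mismatch: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map labels to consecutive 1..k by order of first appearance."""
    remap: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return out, len(remap)


def _kmedoids(D: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Voronoi-style alternation: assign each point to its nearest medoid, then
    move each medoid to the point minimizing the within-cluster distance
    sum.  Seeded greedy (maxmin) initialization for determinism.
    """
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        d_near[medoids] = -1
        medoids.append(int(d_near.argmax()))
    medoids = np.sort(np.array(medoids))

    for _ in range(max_iter):
        assign = D[:, medoids].argmin(axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:  # rescue an empty cluster with the worst-fit point
                worst = int(D[np.arange(n), medoids[assign]].argmax())
                new_medoids[c] = worst
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(within.argmin())]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return D[:, medoids].argmin(axis=1) + 1


def _dynamic_cut(
    Z: np.ndarray, D: np.ndarray, min_cluster_size: int = 5, height_quantile: float = 0.99
) -> np.ndarray:
    """Adaptive dendrogram cut with a minimum cluster size.

    A simplified variant of dynamic branch cutting: the tree is first cut
    just below its top joins (at ``height_quantile`` of the maximum merge
    height), so the number of branches emerges from the tree shape rather
    than a requested k; branches smaller than ``min_cluster_size`` are then
    dissolved into the nearest surviving branch by average distance.
    """
    heights = Z[:, 2]
    cut = height_quantile * heights.max() if heights.size else 0.0
    labels = fcluster(Z, t=cut, criterion="distance")
    uniq, counts = np.unique(labels, return_counts=True)
    big = uniq[counts >= min_cluster_size]
    if big.size == 0:  # every branch tiny: keep the largest only
        big = uniq[[counts.argmax()]]
    small_points = np.flatnonzero(~np.isin(labels, big))
    for i in small_points:
        mean_d = [D[i, labels == b].mean() for b in big]
        labels[i] = big[int(np.argmin(mean_d))]
    out, _ = _relabel(labels)
    return out


def candidate_partitions(
    S: SimilarityMatrix, k_min: int = 2, k_max: int = 10, seed: int = 0
) -> list[EnsembleCandidate]:
    """Candidate partitions of the merged similarity matrix.

    Hierarchical (average linkage) and medoid candidates are produced at
    every k in ``[k_min, k_max]``; the dynamic cut contributes a single
    candidate whose k emerges from the dendrogram shape.
    """
    n = len(S.sample_ids)
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be below the sample count {n}")
    if k_min < 1 or k_min > k_max:
        raise ValidationError("need 1 <= k_min <= k_max")
    D = 1.0 - S.values
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")

    candidates: list[EnsembleCandidate] = []
    # cut_tree rather than fcluster(maxclust): it cuts between merges, so it
    # still yields exactly k non-empty clusters when merge heights tie
    cuts = cut_tree(Z, n_clusters=list(range(k_min, k_max + 1)))
    for i, k in enumerate(range(k_min, k_max + 1)):
        labels, k_eff = _relabel(cuts[:, i])
        candidates.append(EnsembleCandidate("hierarchical", labels, k_eff))
    seeds = np.random.SeedSequence(seed).generate_state(k_max - k_min + 1)
    for i, k in enumerate(range(k_min, k_max + 1)):
        labels, k_eff = _relabel(_kmedoids(D, k, seed=int(seeds[i] % 2**31)))
        candidates.append(EnsembleCandidate("medoid", labels, k_eff))
    dyn = _dynamic_cut(Z, D)
    candidates.append(EnsembleCandidate("dynamic-tree-cut", dyn, int(dyn.max())))
    return candidates


def ensemble_select(
    candidates: Sequence[EnsembleCandidate],
    per_type_partitions: Sequence[Sequence[int]],
) -> tuple[np.ndarray, int]:
    """Pick the candidate agreeing most (mean ARI) with the per-type
    partitions; ties favor fewer clusters, then hierarchical < medoid <
    dynamic-tree-cut.  Single-cluster candidates only win if nothing else
    beats them."""
    if not candidates:
        raise ValidationError("empty candidate list")
    if not per_type_partitions:
        raise ValidationError("need at least one per-type partition")

    best_key: tuple | None = None
    best: EnsembleCandidate | None = None
    for cand in candidates:
        cand.agreement = float(
            np.mean([agreement(cand.labels, p) for p in per_type_partitions])
        )
        # a k=1 candidate scores ARI 0 against any partition, so it only
        # prevails when no multi-cluster candidate agrees better
        key = (
            -cand.agreement,
            cand.k,
            _ALGO_RANK.get(cand.algorithm, len(_ALGO_RANK)),
        )
        if best_key is None or key < best_key:
            best_key, best = key, cand
    assert best is not None
    labels, k = _relabel(best.labels)
    return labels, k
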