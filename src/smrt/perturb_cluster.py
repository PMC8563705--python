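"""Perturbation clustering of a single (reduced) omics layer.

The number of clusters is chosen by stability under Gaussian noise: for each
candidate k the unperturbed data is partitioned once (k-means) to give a
binary co-clustering ("connectivity") matrix, then the data is repeatedly
perturbed with additive Gaussian noise and re-partitioned, and the binary
connectivity matrices of the perturbed runs are averaged.  A partition whose
pairwise co-memberships survive perturbation — the averaged matrix stays
close to the original 0/1 pattern — is stable; the k with the highest
stability wins, smallest k on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core_io import ValidationError
from .reduction import ReducedMatrix

__all__ = [
    "ConnectivityMatrix",
    "PartitionResult",
    "perturb",
    "connectivity_from_labels",
    "perturbed_connectivity",
    "stability_score",
    "cluster_single",
    "default_noise_sd",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric sample x sample matrix of co-clustering frequencies in [0,1]
    with unit diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"connectivity shape {v.shape} != ({n}, {n})")
        if not np.array_equal(v, v.T):
            raise ValidationError("connectivity matrix must be exactly symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValidationError("connectivity diagonal must be 1")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("connectivity entries must lie in [0, 1]")
        self.values = v


@dataclass
class PartitionResult:
    """Chosen partition of one data type with its stability diagnostics."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int
    stability: float
    connectivity: ConnectivityMatrix
    per_k_stability: dict[int, float]


def perturb(X: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise of standard deviation ``noise_sd`` per entry."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if noise_sd == 0:
        return np.array(X, copy=True)
    return X + rng.normal(0.0, noise_sd, size=X.shape)


def connectivity_from_labels(labels: Sequence[int]) -> np.ndarray:
    """Binary co-membership matrix: entry 1 iff the two samples share a label."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValidationError("need at least one label")
    return (lab[:, None] == lab[None, :]).astype(float)


def _kmeans_labels(X: np.ndarray, k: int, seed: int, n_init: int = 10) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)


def perturbed_connectivity(
    X: np.ndarray,
    k: int,
    n_perturb: int,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Mean of binary connectivity matrices over ``n_perturb`` noisy replicates.

    Each replicate draws fresh noise and re-runs k-means from a replicate-
    specific seed, so results do not depend on evaluation order.
    """
    n = X.shape[0]
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of samples {n}")
    if n_perturb < 1:
        raise ValidationError("n_perturb must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_perturb)
    acc = np.zeros((n, n))
    for rep in range(n_perturb):
        rng = np.random.default_rng(child_seeds[2 * rep])
        Xp = perturb(X, noise_sd, rng)
        labels = _kmeans_labels(Xp, k, seed=int(child_seeds[2 * rep + 1] % 2**31))
        acc += connectivity_from_labels(labels)
    acc /= n_perturb
    np.fill_diagonal(acc, 1.0)
    return acc


def stability_score(original: np.ndarray, perturbed: np.ndarray) -> float:
    """1 minus the mean absolute off-diagonal discrepancy between the
    original and perturbed-average connectivity matrices; 1 = perfectly
    stable."""
    a = np.asarray(original, dtype=float)
    b = np.asarray(perturbed, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValidationError("need at least two samples")
    diff = np.abs(a - b)
    off_sum = diff.sum() - np.trace(diff)
    return float(1.0 - off_sum / (n * (n - 1)))


def default_noise_sd(scores: np.ndarray) -> float:
    """Median of the feature-wise standard deviations of the reduced data."""
    sd = float(np.median(scores.std(axis=0, ddof=1)))
    if sd == 0:
        raise ValidationError("zero variance: all samples are identical")
    return sd


def cluster_single(
    X: ReducedMatrix,
    k_min: int = 2,
    k_max: int = 10,
    n_perturb: int = 50,
    noise_sd: float | None = None,
    seed: int = 0,
) -> PartitionResult:
    """Perturbation clustering of one reduced layer.

    For every k in ``[k_min, k_max]`` the unperturbed scores are partitioned
    by k-means, the binary connectivity is compared with the average
    connectivity over ``n_perturb`` Gaussian perturbations, and the k with
    the highest stability is returned.  Exact stability ties resolve to the
    larger k: when classes are strongly separated, merging two true classes
    can be perfectly stable too (the same merge wins in every replicate),
    whereas splitting a homogeneous cluster never is — so the finest
    maximally stable partition is the structure-revealing one.

    ``noise_sd`` defaults to the median feature-wise standard deviation of
    the scores.
    """
    scores = np.asarray(X.scores, dtype=float)
    n = scores.shape[0]
    if n < 3:
        raise ValidationError("perturbation clustering needs at least 3 samples")
    if np.all(scores == scores[0]):
        raise ValidationError("zero variance: all samples are identical")
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValidationError(
            f"need 2 <= k_min <= k_max <= n-1, got k_min={k_min}, k_max={k_max}, n={n}"
        )
    if noise_sd is None:
        noise_sd = default_noise_sd(scores)

    ss = np.random.SeedSequence(seed)
    per_k_seed = ss.generate_state(2 * (k_max - k_min + 1))

    # only the incumbent's matrices are retained; with ascending k and a
    # non-strict improvement rule, exact ties resolve to the larger k
    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    per_k_stability: dict[int, float] = {}
    for i, k in enumerate(range(k_min, k_max + 1)):
        base = _kmeans_labels(scores, k, seed=int(per_k_seed[2 * i] % 2**31))
        orig = connectivity_from_labels(base)
        pert = perturbed_connectivity(
            scores, k, n_perturb, noise_sd, seed=int(per_k_seed[2 * i + 1])
        )
        stab = stability_score(orig, pert)
        per_k_stability[k] = stab
        if best is None or stab >= best[0]:
            best = (stab, k, base, pert)

    assert best is not None
    stab, k_star, base, pert = best
    # relabel to consecutive 1..k by order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty_like(base)
    for i, lab in enumerate(base):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return PartitionResult(
        sample_ids=list(X.sample_ids),
        labels=labels,
        k=len(remap),
        stability=stab,
        connectivity=ConnectivityMatrix(sample_ids=list(X.sample_ids), values=pert),
        per_k_stability=per_k_stability,
    )
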