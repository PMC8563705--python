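"""Randomized SVD dimension reduction.

Each omics layer is mean-centered per feature and projected onto its top
right-singular subspace, estimated with the randomized range-finder scheme:
a Gaussian projection ``Z = X P``, QR orthogonalization, the small exact SVD
of ``Y = Q' X``, and scores ``X' = X V``.  Power iterations (with a QR
re-orthogonalization each pass) sharpen the estimated subspace when the
spectrum decays slowly.

New samples measured on the same features are projected into the fitted
component space with :func:`rsvd_transform`, which is how the propagated set
of a large cohort is mapped into the sampled set's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import OmicsMatrix, ValidationError

__all__ = ["RsvdModel", "ReducedMatrix", "rsvd_fit", "rsvd_transform", "choose_rank"]


@dataclass
class RsvdModel:
    """Fitted reduction for one layer.

    ``rotation`` holds the estimated right singular vectors V (features x
    rank, orthonormal columns); ``center`` the feature means of the fitting
    set; ``singular_values`` the corresponding non-increasing spectrum of the
    centered fitting matrix.
    """

    feature_ids: list[str]
    rotation: np.ndarray
    singular_values: np.ndarray
    center: np.ndarray
    seed: int

    @property
    def rank(self) -> int:
        return self.rotation.shape[1]

    def truncate(self, rank: int) -> "RsvdModel":
        if not 1 <= rank <= self.rank:
            raise ValidationError(f"cannot truncate rank-{self.rank} model to {rank}")
        return RsvdModel(
            feature_ids=self.feature_ids,
            rotation=self.rotation[:, :rank],
            singular_values=self.singular_values[:rank],
            center=self.center,
            seed=self.seed,
        )


@dataclass
class ReducedMatrix:
    """Samples in component space: ``scores[i]`` are the coordinates of
    ``sample_ids[i]`` along the model's components."""

    sample_ids: list[str]
    scores: np.ndarray


def rsvd_fit(
    X: OmicsMatrix,
    rank: int,
    oversample: int = 10,
    power_iters: int = 2,
    seed: int = 0,
) -> RsvdModel:
    """Fit a randomized SVD of the mean-centered layer.

    Parameters
    ----------
    rank
        Number of components kept, ``1 <= rank <= min(n-1, m)``.
    oversample
        Extra random directions during range finding; improves subspace
        capture at negligible cost.
    power_iters
        Number of power iterations; each multiplies the spectrum gap and is
        followed by a QR re-orthogonalization for stability.
    """
    n, m = X.values.shape
    if not 1 <= rank <= min(n - 1, m):
        raise ValidationError(
            f"rank must be in [1, {min(n - 1, m)}] for a {n}x{m} layer, got {rank}"
        )
    if oversample < 0 or power_iters < 0:
        raise ValidationError("oversample and power_iters must be >= 0")

    center = X.values.mean(axis=0)
    A = X.values - center
    ell = min(rank + oversample, min(n, m))

    rng = np.random.default_rng(seed)
    P = rng.standard_normal((m, ell))
    Z = A @ P
    Q, _ = np.linalg.qr(Z)
    for _ in range(power_iters):
        W, _ = np.linalg.qr(A.T @ Q)
        Q, _ = np.linalg.qr(A @ W)
    Y = Q.T @ A
    _, s, Vt = np.linalg.svd(Y, full_matrices=False)
    return RsvdModel(
        feature_ids=list(X.feature_ids),
        rotation=np.ascontiguousarray(Vt[:rank].T),
        singular_values=s[:rank].copy(),
        center=center,
        seed=seed,
    )


def rsvd_transform(
    model: RsvdModel, X: OmicsMatrix, block_size: int = 4096
) -> ReducedMatrix:
    """Project samples into the model's component space: ``(X - center) V``.

    Features must match the fitting layer exactly (same ids, same order).
    Rows are processed in blocks so a large query matrix is never duplicated
    in memory by the centering step.
    """
    if X.feature_ids != model.feature_ids:
        for got, want in zip(X.feature_ids, model.feature_ids):
            if got != want:
                raise ValidationError(
                    f"feature mismatch: layer has {got!r} where model expects {want!r}"
                )
        raise ValidationError(
            f"feature count mismatch: {len(X.feature_ids)} vs {len(model.feature_ids)}"
        )
    n = X.values.shape[0]
    scores = np.empty((n, model.rank))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        scores[start:stop] = (X.values[start:stop] - model.center) @ model.rotation
    return ReducedMatrix(sample_ids=list(X.sample_ids), scores=scores)


def choose_rank(
    singular_values: Sequence[float],
    max_rank: int = 100,
    var_threshold: float = 0.9,
) -> int:
    """Smallest rank explaining ``var_threshold`` of the (squared) spectrum
    energy, capped at ``max_rank``."""
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0 or not np.any(s > 0):
        raise ValidationError("spectrum has no positive singular value")
    energy = np.cumsum(s**2)
    r = int(np.searchsorted(energy, var_threshold * energy[-1]) + 1)
    return min(r, max_rank, s.size)
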