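"""End-to-end subtyping pipeline.

Two paths share one code route.  The cohort is split into a *sampled* set
(patients present in every layer, at most ``max_sampled`` of them) and a
*propagated* set (everyone else).  Each layer is reduced by randomized SVD
fitted on the sampled rows, perturbation-clustered, and the per-layer
connectivity matrices are merged and ensemble-clustered into final subtypes
for the sampled set.  If the propagated set is non-empty, each of its
patients is projected into every layer's component space and classified by
per-layer kNN vote counting with probabilities averaged across layers.

Connectivity/similarity matrices are only ever allocated over the sampled
set, so memory stays quadratic in ``max_sampled``, not in the cohort size.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .core_io import MultiOmicsDataset, SubtypingResult, ValidationError
from .integrate import candidate_partitions, ensemble_select, merge_connectivities
from .perturb_cluster import PartitionResult, cluster_single
from .propagate import knn_probabilities, propagate_multiomics, select_k, split_samples
from .reduction import choose_rank, rsvd_fit, rsvd_transform

__all__ = ["SmrtParams", "subtype"]

logger = logging.getLogger("smrt")


@dataclass
class SmrtParams:
    """Tunable parameters of a subtyping run.

    ``max_sampled`` bounds the directly clustered set (and hence memory);
    ``k_min``/``k_max`` bound the cluster-number search; ``n_perturb`` and
    ``noise_sd`` control the perturbation stability estimate (``None`` =
    median feature sd of the reduced data); ``var_threshold``/``max_rank``
    set the retained-variance rank policy; ``knn_grid``/``folds`` govern the
    cross-validated neighborhood size for propagation.
    """

    max_sampled: int = 2000
    k_min: int = 2
    k_max: int = 10
    n_perturb: int = 50
    noise_sd: float | None = None
    var_threshold: float = 0.9
    max_rank: int = 100
    oversample: int = 10
    power_iters: int = 2
    knn_k_min: int = 5
    knn_k_max: int = 50
    folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.k_min < 2 or self.k_min > self.k_max:
            raise ValidationError("need 2 <= k_min <= k_max")
        if self.max_sampled < self.k_max + 1:
            raise ValidationError("max_sampled must exceed k_max")
        if min(self.n_perturb, self.max_rank, self.folds, self.knn_k_min) < 1:
            raise ValidationError("all size parameters must be positive")
        if not 0 < self.var_threshold <= 1:
            raise ValidationError("var_threshold must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _log_stage(stage: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0, extras)


def subtype(dataset: MultiOmicsDataset, params: SmrtParams | None = None) -> SubtypingResult:
    """Run the full subtyping workflow on a multi-omics dataset."""
    params = params or SmrtParams()
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(4 * len(dataset.layers) + 8).astype(np.int64)
    next_seed = iter(seeds.tolist())

    t0 = time.perf_counter()
    split = split_samples(dataset, max_sampled=params.max_sampled, seed=int(next(next_seed)))
    n_s = len(split.sampled_ids)
    if n_s < 3:
        raise ValidationError("fewer than 3 samples available for direct clustering")
    _log_stage("split", t0, sampled=n_s, propagated=len(split.propagated_ids))

    models = {}
    sampled_scores = {}
    partitions: dict[str, PartitionResult] = {}
    for layer in dataset.layers:
        t1 = time.perf_counter()
        Xs = layer.subset(split.sampled_ids)
        fit_rank = min(params.max_rank, n_s - 1, layer.n_features)
        model = rsvd_fit(
            Xs,
            rank=fit_rank,
            oversample=params.oversample,
            power_iters=params.power_iters,
            seed=int(next(next_seed)),
        )
        r = choose_rank(
            model.singular_values, max_rank=params.max_rank, var_threshold=params.var_threshold
        )
        model = model.truncate(r)
        models[layer.name] = model
        reduced = rsvd_transform(model, Xs)
        sampled_scores[layer.name] = reduced
        _log_stage("reduce", t1, layer=layer.name, rank=r)

        t1 = time.perf_counter()
        partitions[layer.name] = cluster_single(
            reduced,
            k_min=params.k_min,
            k_max=min(params.k_max, n_s - 1),
            n_perturb=params.n_perturb,
            noise_sd=params.noise_sd,
            seed=int(next(next_seed)),
        )
        _log_stage(
            "cluster", t1, layer=layer.name,
            k=partitions[layer.name].k, stability=round(partitions[layer.name].stability, 4),
        )

    t1 = time.perf_counter()
    merged = merge_connectivities([partitions[l.name].connectivity for l in dataset.layers])
    candidates = candidate_partitions(
        merged, k_min=params.k_min, k_max=min(params.k_max, n_s - 1),
        seed=int(next(next_seed)),
    )
    sampled_labels, k_final = ensemble_select(
        candidates, [partitions[l.name].labels for l in dataset.layers]
    )
    _log_stage("integrate", t1, k=k_final)

    label_of: dict[str, int] = dict(zip(split.sampled_ids, (int(v) for v in sampled_labels)))

    if split.propagated_ids:
        t1 = time.perf_counter()
        per_type_probs = []
        for layer in dataset.layers:
            layer_ids = set(layer.sample_ids)
            queries = [s for s in split.propagated_ids if s in layer_ids]
            if not queries:
                continue
            q_scores = rsvd_transform(models[layer.name], layer.subset(queries))
            k_nn = select_k(
                sampled_scores[layer.name],
                sampled_labels,
                k_grid=range(params.knn_k_min, params.knn_k_max + 1),
                folds=params.folds,
                seed=int(next(next_seed)),
            )
            per_type_probs.append(
                knn_probabilities(sampled_scores[layer.name], sampled_labels, q_scores, k_nn)
            )
            _log_stage("knn", t1, layer=layer.name, k_nn=k_nn, queries=len(queries))
        propagated_labels = propagate_multiomics(per_type_probs)
        missing = [s for s in split.propagated_ids if s not in propagated_labels]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} appears in no layer")
        label_of.update(propagated_labels)
        _log_stage("propagate", t1, n=len(propagated_labels))

    final = np.array([label_of[s] for s in dataset.all_samples])
    # compress to consecutive 1..k in case a subtype received no member
    uniq = np.unique(final)
    final = np.searchsorted(uniq, final) + 1

    return SubtypingResult(
        sample_ids=list(dataset.all_samples),
        final_labels=final,
        per_type_partitions=partitions,
        merged_similarity=merged,
        sampled_ids=split.sampled_ids,
        propagated_ids=split.propagated_ids,
        parameters={**params.to_dict(), "ranks": {n: m.rank for n, m in models.items()}},
    )
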