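"""Evaluation statistics for discovered subtypes.

Survival difference between subtypes is assessed with a Cox proportional-
hazards likelihood-ratio test (subtype membership as a categorical
covariate, largest group as reference).  Partition agreement uses the
adjusted Rand index (see :mod:`smrt.integrate`) and normalized mutual
information.  A transcribed benchmark table of Cox p-values for nine
subtyping methods over 39 cancer cohorts ships with the package for the
significance-count summaries and the rank-sum comparison between methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import mannwhitneyu
from sklearn.metrics import normalized_mutual_info_score

from .core_io import SurvivalTable, ValidationError

__all__ = [
    "PvalueTable",
    "MethodSummary",
    "survival_pvalue",
    "nmi",
    "summarize_pvalue_table",
    "compare_methods_wilcoxon",
    "load_benchmark_pvalues",
]


@dataclass
class PvalueTable:
    """Datasets x methods matrix of Cox p-values."""

    datasets: list[str]
    methods: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.datasets), len(self.methods)):
            raise ValidationError("p-value table shape mismatch")
        if np.any(~np.isfinite(v)) or v.min() < 0 or v.max() > 1:
            raise ValidationError("p-values must lie in [0, 1] with no missing cells")
        self.values = v

    def column(self, method: str) -> np.ndarray:
        if method not in self.methods:
            raise ValidationError(f"unknown method {method!r}")
        return self.values[:, self.methods.index(method)]


@dataclass
class MethodSummary:
    method: str
    n_significant: int
    n_best_and_significant: int
    n_datasets_no_method_significant: int
    alpha: float


def survival_pvalue(labels: Sequence[int], survival: SurvivalTable) -> float:
    """Likelihood-ratio p-value of subtype membership in a Cox model.

    ``labels`` must align with ``survival.sample_ids``; the largest subtype
    is the reference level.
    """
    lab = np.asarray(labels)
    if lab.shape != (len(survival.sample_ids),):
        raise ValidationError("one label per survival record required")
    groups, counts = np.unique(lab, return_counts=True)
    if groups.size < 2:
        raise ValidationError("survival comparison needs at least two subtypes")
    if survival.event.sum() == 0:
        raise ValidationError("all observations censored; Cox model undefined")
    reference = groups[counts.argmax()]
    df = pd.DataFrame({"time": survival.time, "event": survival.event})
    for g in groups:
        if g != reference:
            df[f"grp_{g}"] = (lab == g).astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.log_likelihood_ratio_test().p_value)


def nmi(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Normalized mutual information (arithmetic-mean normalization).

    A constant labeling has zero entropy and scores 0 against any
    non-constant partner.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError(f"label length mismatch: {a.shape} vs {b.shape}")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def summarize_pvalue_table(
    table: PvalueTable, method: str, alpha: float = 0.05
) -> MethodSummary:
    """Significance-count summary for one method column.

    ``n_significant`` counts datasets with p < alpha; ``n_best_and_significant``
    those where the method is additionally strictly smallest in its row;
    ``n_datasets_no_method_significant`` counts rows where no method reaches
    alpha (a table-level quantity, identical for every method).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    col = table.column(method)
    sig = col < alpha
    others = np.delete(table.values, table.methods.index(method), axis=1)
    strictly_best = col < others.min(axis=1)
    no_method = (table.values >= alpha).all(axis=1)
    return MethodSummary(
        method=method,
        n_significant=int(sig.sum()),
        n_best_and_significant=int((sig & strictly_best).sum()),
        n_datasets_no_method_significant=int(no_method.sum()),
        alpha=alpha,
    )


def compare_methods_wilcoxon(table: PvalueTable, method: str) -> float:
    """One-tailed rank-sum p-value that ``method``'s p-values are smaller
    than the pooled p-values of all other methods."""
    if len(table.methods) < 2:
        raise ValidationError("need at least two methods to compare")
    col = table.column(method)
    pooled = np.delete(table.values, table.methods.index(method), axis=1).ravel()
    return float(mannwhitneyu(col, pooled, alternative="less").pvalue)


def load_benchmark_pvalues() -> PvalueTable:
    """Bundled Cox p-values of nine subtyping methods on 39 cancer cohorts
    (37 TCGA, 2 METABRIC)."""
    with resources.files("smrt.data").joinpath("cox_pvalues_39x9.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return PvalueTable(
        datasets=list(df.index), methods=list(df.columns), values=df.to_numpy()
    )
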