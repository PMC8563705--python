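"""Domain containers and disk formats for multi-omics subtyping.

An omics *layer* is one molecular platform (mRNA, DNA methylation, miRNA,
copy number, ...) stored as a samples x features matrix.  Subtyping operates
on one or more layers that share (some) sample identifiers, optionally with
a survival table for downstream evaluation.

File formats are deliberately plain: CSV matrices with sample ids in the
first column and feature ids in the header row, and a three-column survival
CSV (``id,time,event``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "SurvivalTable",
    "SubtypingResult",
    "read_omics_csv",
    "align_layers",
    "read_survival",
    "read_labels",
    "write_result",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """One omics layer: ``values[i, j]`` is feature ``feature_ids[j]``
    measured in sample ``sample_ids[i]``.  Units are platform-specific."""

    name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, f"sample id in layer {self.name!r}")
        _check_unique(self.feature_ids, f"feature id in layer {self.name!r}")
        n, m = len(self.sample_ids), len(self.feature_ids)
        if self.values.shape != (n, m):
            raise ValidationError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match {n} samples x {m} features"
            )
        if n < 2 or m < 1:
            raise ValidationError(
                f"layer {self.name!r}: need at least 2 samples and 1 feature"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"layer {self.name!r}: non-finite value for sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset(self, ids: Sequence[str]) -> "OmicsMatrix":
        """Rows restricted/reordered to ``ids`` (each must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise ValidationError(
                f"sample {exc.args[0]!r} absent from layer {self.name!r}"
            ) from None
        return OmicsMatrix(
            name=self.name,
            sample_ids=list(ids),
            feature_ids=self.feature_ids,
            values=self.values[rows],
        )


@dataclass
class MultiOmicsDataset:
    """A collection of layers sharing sample identifiers.

    ``common_samples`` are present in every layer (the direct-clustering
    candidates); ``all_samples`` is the union across layers.  Both are held
    in sorted order so repeated runs see identical orderings.
    """

    layers: list[OmicsMatrix]
    common_samples: list[str] = field(init=False)
    all_samples: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("need at least one omics layer")
        names = [lay.name for lay in self.layers]
        _check_unique(names, "layer name")
        common = set(self.layers[0].sample_ids)
        union = set(self.layers[0].sample_ids)
        for lay in self.layers[1:]:
            ids = set(lay.sample_ids)
            common &= ids
            union |= ids
        if len(self.layers) > 1 and not common:
            raise ValidationError(
                "no sample is present in every layer; integration impossible"
            )
        self.common_samples = sorted(common)
        self.all_samples = sorted(union)

    def layer(self, name: str) -> OmicsMatrix:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)


@dataclass
class SurvivalTable:
    """Right-censored survival data: time in days, event 1=observed 0=censored."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample id in survival table")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValidationError("survival columns must match the id column length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValidationError("survival times must be finite and >= 0")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValidationError("event indicator must be 0 or 1")

    def lookup(self, ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise ValidationError(
                f"sample {exc.args[0]!r} has no survival record"
            ) from None
        return self.time[rows], self.event[rows]


@dataclass
class SubtypingResult:
    """Full output of one subtyping run.

    ``final_labels`` maps every sample in the dataset union to a subtype
    (consecutive integers starting at 1).  ``per_type_partitions`` keeps the
    single-layer partitions, ``merged_similarity`` the averaged connectivity
    over the sampled set, and ``parameters`` the complete parameter record
    including the seed, so the run can be reproduced exactly.
    """

    sample_ids: list[str]
    final_labels: np.ndarray
    per_type_partitions: dict  # layer name -> PartitionResult
    merged_similarity: object  # ConnectivityMatrix over the sampled set
    sampled_ids: list[str]
    propagated_ids: list[str]
    parameters: dict

    def __post_init__(self) -> None:
        self.final_labels = np.asarray(self.final_labels, dtype=int)
        if self.final_labels.shape != (len(self.sample_ids),):
            raise ValidationError("one label per sample required")
        uniq = np.unique(self.final_labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValidationError("labels must be consecutive integers from 1")
        if set(self.sampled_ids) & set(self.propagated_ids):
            raise ValidationError("sampled and propagated sets must be disjoint")
        if set(self.sampled_ids) | set(self.propagated_ids) != set(self.sample_ids):
            raise ValidationError("sampled + propagated must cover all samples")

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "subtype": self.final_labels})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_omics_csv(
    path: str | Path, name: str, drop_missing_features: bool = False
) -> OmicsMatrix:
    """Read one layer from CSV (row 1 = feature header, column 1 = sample ids).

    Row and column order are preserved.  Missing or non-numeric cells are
    rejected with the offending sample/feature named; with
    ``drop_missing_features`` such feature columns are silently dropped
    instead (an entirely unusable matrix still errors).
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty matrix")
    raw = df.to_numpy()
    values = np.empty(df.shape, dtype=float)
    keep: list[int] = []
    for j, feat in enumerate(df.columns):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            if drop_missing_features:
                continue
            raise ValidationError(
                f"{path}: non-numeric value {raw[bad[0], j]!r} at sample "
                f"{df.index[bad[0]]!r}, feature {feat!r}"
            )
        values[:, j] = col
        keep.append(j)
    if not keep:
        raise ValidationError(f"{path}: every feature has missing values")
    return OmicsMatrix(
        name=name,
        sample_ids=list(df.index),
        feature_ids=[df.columns[j] for j in keep],
        values=values[:, keep],
    )


def write_omics_csv(matrix: OmicsMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids
    ).to_csv(path)


def align_layers(matrices: Sequence[OmicsMatrix]) -> MultiOmicsDataset:
    """Bundle layers, computing the (sorted) common and union sample sets."""
    return MultiOmicsDataset(layers=list(matrices))


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path)
    required = {"id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: survival CSV needs columns id,time,event")
    return SurvivalTable(
        sample_ids=list(df["id"].astype(str)),
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
    )


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    return dict(zip(df["sample_id"].astype(str), df["subtype"].astype(int)))


def write_result(result: SubtypingResult, out_dir: str | Path) -> dict[str, Path]:
    """Write labels CSV and a JSON parameter/provenance record.

    Returns the paths written, keyed by artifact kind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_path = out / "subtypes.csv"
    result.labels_frame().to_csv(labels_path, index=False)

    record = {
        "parameters": result.parameters,
        "n_samples": len(result.sample_ids),
        "n_subtypes": int(result.final_labels.max()),
        "sampled_ids": result.sampled_ids,
        "propagated_ids": result.propagated_ids,
        "per_type": {
            name: {
                "k": int(p.k),
                "stability": float(p.stability),
                "per_k_stability": {str(k): float(v) for k, v in p.per_k_stability.items()},
            }
            for name, p in result.per_type_partitions.items()
        },
    }
    json_path = out / "result.json"
    json_path.write_text(json.dumps(record, indent=2))

    sim_path = out / "merged_similarity.csv"
    sim = result.merged_similarity
    pd.DataFrame(sim.values, index=sim.sample_ids, columns=sim.sample_ids).to_csv(sim_path)
    return {"labels": labels_path, "record": json_path, "similarity": sim_path}
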