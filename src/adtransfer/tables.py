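"""Shared tabular containers: subject metadata and subjects-by-features matrices.

The study operates on two cohorts. The *training* cohort is a single-site
case-control sample (healthy controls vs probable AD). The *clinic* cohort is
a four-site memory-clinic sample with three clinical groups of increasing
severity: subjective memory complaints (SMC), mild cognitive impairment (MCI)
and AD. Every numeric feature belongs to exactly one of nine named feature
groups, each tied to an MRI modality (anatomical, diffusion or rs-fMRI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TRAINING_LABELS = ("HC", "AD")
CLINIC_LABELS = ("SMC", "MCI", "AD")
COHORTS = ("training", "clinic")

#: the nine feature groups and their default dimensionality.  The voxel-wise
#: low-frequency power map in a real brain mask has ~1.4e5 voxels; the
#: pipeline is dimension-generic, so the default synthetic "brain" uses 500
#: voxels (configurable).
FEATURE_GROUPS: dict[str, dict] = {
    "Grey matter density": {"n_features": 48, "modality": "anatomical"},
    "Subcortical volumes": {"n_features": 14, "modality": "anatomical"},
    "Cortical thickness": {"n_features": 68, "modality": "anatomical"},
    "Fractional anisotropy": {"n_features": 20, "modality": "diffusion"},
    "Mean diffusivity": {"n_features": 20, "modality": "diffusion"},
    "Axial diffusivity": {"n_features": 20, "modality": "diffusion"},
    "Radial diffusivity": {"n_features": 20, "modality": "diffusion"},
    "Functional connectivity": {"n_features": 2415, "modality": "rsfmri"},
    "ALFF": {"n_features": 500, "modality": "rsfmri"},
}

MODALITY_OF_GROUP = {g: spec["modality"] for g, spec in FEATURE_GROUPS.items()}

#: combined models pool the groups of one modality (or all of them)
COMBINED_MODELS: dict[str, tuple[str, ...]] = {
    "Combined anatomical MRI": tuple(
        g for g, s in FEATURE_GROUPS.items() if s["modality"] == "anatomical"
    ),
    "Combined diffusion MRI": tuple(
        g for g, s in FEATURE_GROUPS.items() if s["modality"] == "diffusion"
    ),
    "Combined rs-fMRI": tuple(
        g for g, s in FEATURE_GROUPS.items() if s["modality"] == "rsfmri"
    ),
    "Multimodal MRI": tuple(FEATURE_GROUPS),
}


@dataclass
class SubjectTable:
    """Per-subject demographics, site and clinical label for one cohort.

    Wraps a DataFrame with columns ``subject_id, cohort, site, label, age,
    sex, education, mmse, cdr, gds``.
    """

    data: pd.DataFrame

    REQUIRED = (
        "subject_id",
        "cohort",
        "site",
        "label",
        "age",
        "sex",
        "education",
        "mmse",
        "cdr",
        "gds",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"subject table missing columns: {missing}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dups[:5]}")
        cohorts = set(self.data["cohort"].unique())
        if not cohorts <= set(COHORTS):
            raise ValueError(f"unknown cohort values: {cohorts - set(COHORTS)}")
        for cohort, allowed in (("training", TRAINING_LABELS), ("clinic", CLINIC_LABELS)):
            sub = self.data[self.data["cohort"] == cohort]
            bad = set(sub["label"].unique()) - set(allowed)
            if bad:
                raise ValueError(f"labels {bad} not valid for {cohort} cohort")
        if (self.data["age"] <= 0).any():
            raise ValueError("ages must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    @property
    def sites(self) -> np.ndarray:
        return self.data["site"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SubjectTable":
        return SubjectTable(self.data.loc[np.asarray(mask)].reset_index(drop=True))

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "SubjectTable":
        return cls(pd.read_csv(path, sep=sep))


@dataclass
class FeatureTable:
    """Subjects-by-features numeric matrix plus a feature-to-group mapping."""

    values: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        unmapped = [c for c in self.values.columns if c not in self.group_of]
        if unmapped:
            raise ValueError(f"features without a group: {unmapped[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for c in self.values.columns:
            g = self.group_of[c]
            if g not in seen:
                seen.append(g)
        return seen

    def matrix(self, groups: Iterable[str] | None = None) -> np.ndarray:
        if groups is None:
            return self.values.to_numpy(dtype=float)
        return self.values[self.columns_of(groups)].to_numpy(dtype=float)

    def columns_of(self, groups: Iterable[str]) -> list[str]:
        groups = list(groups)
        unknown = set(groups) - set(self.group_of.values())
        if unknown:
            raise KeyError(f"unknown feature groups: {sorted(unknown)}")
        gset = set(groups)
        return [c for c in self.values.columns if self.group_of[c] in gset]

    def group_indices(self, columns: list[str] | None = None) -> np.ndarray:
        """Integer group index per feature, in first-appearance order."""
        cols = columns if columns is not None else list(self.values.columns)
        order: dict[str, int] = {}
        idx = np.empty(len(cols), dtype=np.int64)
        for j, c in enumerate(cols):
            g = self.group_of[c]
            idx[j] = order.setdefault(g, len(order))
        return idx

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        new = pd.DataFrame(values, index=self.values.index, columns=self.values.columns)
        return FeatureTable(new, dict(self.group_of))

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[np.asarray(mask)].reset_index(drop=True), dict(self.group_of)
        )

    def concat_features(self, other: "FeatureTable") -> "FeatureTable":
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ValueError(f"duplicate feature names: {sorted(overlap)[:5]}")
        values = pd.concat([self.values, other.values.set_axis(self.values.index)], axis=1)
        return FeatureTable(values, {**self.group_of, **other.group_of})

    # ------------------------------------------------------------------
    # delimited-text round trip: values table + sidecar group-mapping file
    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        path = Path(path)
        self.values.to_csv(path, sep=sep, index=False)
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        sidecar.write_text(json.dumps(self.group_of, indent=0))

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "FeatureTable":
        path = Path(path)
        values = pd.read_csv(path, sep=sep)
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        group_of = json.loads(sidecar.read_text())
        return cls(values, group_of)


def check_alignment(features: FeatureTable, subjects: SubjectTable) -> None:
    if len(features) != len(subjects):
        raise ValueError(
            f"feature table has {len(features)} rows but subject table has {len(subjects)}"
        )


def binary_outcome(labels: np.ndarray, positive: str, negative: str) -> np.ndarray:
    """Encode the more-severe class as 1 and the less-severe as 0."""
    labels = np.asarray(labels)
    known = np.isin(labels, [positive, negative])
    if not known.all():
        raise ValueError(f"labels outside {{{negative}, {positive}}} present")
    return (labels == positive).astype(np.int64)
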