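"""Shared in-memory containers for the pipeline.

A :class:`FeatureTable` bundles three aligned pandas DataFrames: per-feature
metadata (MaxQuant-style flags, peptide counts, leading protein), a
features x samples matrix of log2 intensities with NaN for missing values,
and the sample design (plex, timepoint, treatment, pooled flag, loading
scale).  All downstream statistics operate on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ["plex_or_run_id", "timepoint", "treatment", "is_pooled", "loading_scale"]

META_COLUMNS = [
    "kind",
    "is_reverse",
    "is_contaminant",
    "only_by_site",
    "n_peptides",
    "n_unique_peptides",
    "leading_protein",
    "site_position",
]


def make_design(
    sample_ids: list[str],
    treatments: list[str | None],
    *,
    plex_or_run_id: str = "plex1",
    timepoint: str = "day14",
    pooled: list[bool] | None = None,
    loading_scales: list[float] | None = None,
) -> pd.DataFrame:
    """Assemble a sample-design table indexed by unique sample id."""
    n = len(sample_ids)
    if len(set(sample_ids)) != n:
        raise ValueError("sample ids must be unique")
    design = pd.DataFrame(
        {
            "plex_or_run_id": plex_or_run_id,
            "timepoint": timepoint,
            "treatment": treatments,
            "is_pooled": pooled if pooled is not None else [False] * n,
            "loading_scale": loading_scales if loading_scales is not None else [1.0] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    if design.index.has_duplicates:
        raise ValueError("sample ids must be unique")
    for plex, sub in design.groupby("plex_or_run_id"):
        if int(sub["is_pooled"].sum()) > 1:
            raise ValueError(f"more than one pooled sample in plex {plex!r}")
    non_pooled = design[~design["is_pooled"]]
    if non_pooled["treatment"].isna().any():
        raise ValueError("every non-pooled sample needs a treatment")
    if (design["loading_scale"] <= 0).any():
        raise ValueError("loading scales must be strictly positive")


@dataclass
class FeatureTable:
    """Features x samples log2 intensity matrix with metadata and design."""

    meta: pd.DataFrame
    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.meta.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if not self.meta.index.equals(self.values.index):
            raise ValueError("meta and values must share the same feature index")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("value columns must match design sample ids in order")
        validate_design(self.design)
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("intensities must be finite where present")

    @property
    def n_features(self) -> int:
        return len(self.meta)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    def analytic_samples(self) -> list[str]:
        """Sample ids excluding the pooled reference channel(s)."""
        return list(self.design.index[~self.design["is_pooled"]])

    def subset_features(self, keep: pd.Index | list[str]) -> "FeatureTable":
        keep = pd.Index(keep)
        return FeatureTable(self.meta.loc[keep], self.values.loc[keep], self.design)

    def subset_samples(self, keep: list[str]) -> "FeatureTable":
        return FeatureTable(self.meta, self.values[keep], self.design.loc[keep])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.meta.copy(), self.values.copy(), self.design.copy())


@dataclass
class SeedList:
    """A labelled set of uppercase gene symbols used to seed networks."""

    label: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = {str(m).upper() for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (uppercase symbols) with a provenance string."""

    sets: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            up = {str(m).upper() for m in members}
            if not up:
                raise ValueError(f"gene set {name!r} is empty")
            if name in cleaned:
                raise ValueError(f"duplicate gene-set name {name!r}")
            cleaned[name] = up
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
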