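"""Filtering, normalization, outlier-removal and imputation cascade.

The canonical stage order is: flag filters -> drop pooled channel ->
zeros-to-missing -> global observed-fraction filter -> median normalization
-> (optional quantile normalization) -> per-condition missingness filter ->
PCA-based sample-outlier removal -> downshifted-normal imputation.  Filters
must see missingness before imputation erases it, and normalizing before
imputing keeps the imputation calibrated per sample.

Every stage returns an updated :class:`PreprocessReport` recording exactly
which rule removed which feature or sample, so the survivor counts the
analysis reports are fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .datatypes import FeatureTable


@dataclass
class PreprocessReport:
    """Per-rule removal bookkeeping for one table's cascade."""

    removed: dict[str, list[str]] = field(default_factory=dict)
    samples_removed: list[str] = field(default_factory=list)
    imputed_cells: int = 0
    sample_offsets: dict[str, float] = field(default_factory=dict)

    def record(self, rule: str, feature_ids: list[str]) -> None:
        self.removed.setdefault(rule, []).extend(feature_ids)

    def n_removed(self, rule: str | None = None) -> int:
        if rule is not None:
            return len(self.removed.get(rule, []))
        return sum(len(v) for v in self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rule, fid) for rule, fids in self.removed.items() for fid in fids
        ]
        return pd.DataFrame(rows, columns=["rule", "feature_id"])


def apply_flag_filters(
    table: FeatureTable, report: PreprocessReport | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove decoy/contaminant/site-only rows and low-evidence proteins.

    Protein tables drop any row flagged reverse, contaminant or
    only-identified-by-site, and additionally require at least one unique
    peptide and more than one peptide.  Phosphosite tables drop only rows
    whose leading protein is a contaminant.
    """
    report = report or PreprocessReport()
    meta = table.meta
    is_protein = meta["kind"].eq("protein")

    flagged = meta["is_contaminant"] | (
        is_protein & (meta["is_reverse"] | meta["only_by_site"])
    )
    low_evidence = is_protein & (
        (meta["n_unique_peptides"] < 1) | (meta["n_peptides"] <= 1)
    )
    report.record("flags", list(meta.index[flagged]))
    report.record("peptide_evidence", list(meta.index[low_evidence & ~flagged]))
    keep = meta.index[~(flagged | low_evidence)]
    return table.subset_features(keep), report


class DegenerateDesignError(ValueError):
    pass


def drop_pooled(table: FeatureTable) -> FeatureTable:
    """Remove pooled reference channel(s); error if <2 samples per group remain."""
    keep = table.analytic_samples()
    if not keep:
        raise DegenerateDesignError("design contains only pooled samples")
    design = table.design.loc[keep]
    counts = design["treatment"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise DegenerateDesignError(
            "fewer than 2 samples per treatment group after removing pooled channel"
        )
    return table.subset_samples(keep)


def zeros_to_missing(table: FeatureTable) -> FeatureTable:
    """Exact-zero intensities (raw zeros carried through log2) become missing."""
    values = table.values.mask(table.values.eq(0.0))
    return FeatureTable(table.meta, values, table.design)


def filter_global_observed(
    table: FeatureTable, min_frac: float = 0.5, report: PreprocessReport | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Keep features observed in strictly more than ``min_frac`` of analytic samples."""
    if min_frac <= 0:
        raise ValueError("min_frac must be positive")
    report = report or PreprocessReport()
    analytic = table.analytic_samples()
    observed_frac = table.values[analytic].notna().mean(axis=1)
    keep = table.meta.index[observed_frac > min_frac]
    report.record("global_observed", list(table.meta.index.difference(keep, sort=False)))
    return table.subset_features(keep), report


def filter_condition_missing(
    table: FeatureTable,
    max_frac: float = 0.2,
    scope: str = "group",
    report: PreprocessReport | None = None,
) -> tuple[FeatureTable, PreprocessReport]:
    """Drop features whose missing fraction strictly exceeds ``max_frac``.

    With scope='group' (default) the rule applies within each treatment
    group separately; with scope='all' across all analytic samples.
    """
    if not (0 <= max_frac < 1):
        raise ValueError("max_frac must lie in [0, 1)")
    report = report or PreprocessReport()
    design = table.design
    analytic = table.analytic_samples()
    drop = pd.Series(False, index=table.meta.index)
    if scope == "group":
        for _, sub in design.loc[analytic].groupby("treatment"):
            frac = table.values[list(sub.index)].isna().mean(axis=1)
            drop |= frac > max_frac
    elif scope == "all":
        drop = table.values[analytic].isna().mean(axis=1) > max_frac
    else:
        raise ValueError("scope must be 'group' or 'all'")
    report.record("condition_missing", list(table.meta.index[drop]))
    return table.subset_features(list(table.meta.index[~drop])), report


def median_normalize(
    table: FeatureTable, report: PreprocessReport | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Equalize per-sample medians on the log2 scale.

    Each sample's median of observed values is subtracted and the grand
    median of those medians added back, so all sample medians coincide
    afterwards.  Idempotent; preserves within-sample ordering.
    """
    report = report or PreprocessReport()
    medians = table.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"sample(s) with no observed values: {bad}")
    grand = float(medians.median())
    offsets = grand - medians
    values = table.values.add(offsets, axis=1)
    for sid, off in offsets.items():
        report.sample_offsets[sid] = report.sample_offsets.get(sid, 0.0) + float(off)
    return FeatureTable(table.meta, values, table.design), report


def quantile_normalize(table: FeatureTable) -> FeatureTable:
    """Map each sample's observed values onto the mean quantile function.

    The reference distribution is the across-sample mean of sorted observed
    values (interpolated when samples have unequal observed counts);
    missing entries stay missing.
    """
    values = table.values
    grid = np.linspace(0, 1, 101)
    quantiles = np.vstack(
        [np.nanquantile(values[c].to_numpy(dtype=float), grid) for c in values.columns]
    )
    reference = quantiles.mean(axis=0)

    out = values.copy()
    for c in values.columns:
        col = values[c]
        obs = col.dropna()
        if len(obs) < 2:
            continue
        ranks = obs.rank(method="average")
        q = (ranks - 1) / (len(obs) - 1)
        out.loc[obs.index, c] = np.interp(q, grid, reference)
    return FeatureTable(table.meta, out, table.design)


class InsufficientDataError(ValueError):
    pass


def detect_outlier_samples(table: FeatureTable, z_threshold: float = 4.0) -> list[str]:
    """Flag samples far from the centroid in PC1-2 score space.

    PCA is computed on complete features only (any row with a missing value
    is excluded), samples mean-centred per feature.  A sample is flagged
    when the robust z-score (median/MAD) of its Euclidean distance from the
    score-space centroid exceeds ``z_threshold``.  Because centroid
    distances of a homogeneous design form a tight chi-like cloud whose MAD
    can be a tiny fraction of the typical distance, the robust scale is
    floored at 25% of the median distance: a flagged sample must sit at a
    material multiple of the typical distance, not merely outside an
    arbitrarily narrow band.
    """
    analytic = table.analytic_samples()
    if len(analytic) < 3:
        raise InsufficientDataError("need at least 3 analytic samples")
    complete = table.values[analytic].dropna(axis=0)
    if len(complete) < 3:
        raise InsufficientDataError("fewer than 3 complete features for PCA")
    X = complete.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    n_comp = min(2, len(analytic) - 1)
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    centroid = scores.mean(axis=0)
    dist = np.sqrt(((scores - centroid) ** 2).sum(axis=1))
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    scale = max(1.4826 * mad, 0.25 * med)
    if scale == 0:
        return []
    z = (dist - med) / scale
    return [sid for sid, zi in zip(analytic, z) if zi > z_threshold]


def impute_downshifted_normal(
    table: FeatureTable,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int = 0,
    report: PreprocessReport | None = None,
) -> tuple[FeatureTable, PreprocessReport]:
    """Fill missing cells from a per-sample downshifted normal distribution.

    For a sample with observed mean m and standard deviation s, each missing
    entry is an independent draw from Normal(m - shift*s, (width*s)^2).
    Observed entries are never altered.
    """
    report = report or PreprocessReport()
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    for sid in values.columns:
        col = values[sid]
        obs = col.dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {sid!r} has fewer than 2 observed values")
        missing = col.index[col.isna()]
        if len(missing) == 0:
            continue
        m, s = float(obs.mean()), float(obs.std(ddof=1))
        draws = rng.normal(m - shift * s, width * s, size=len(missing))
        values.loc[missing, sid] = draws
        report.imputed_cells += len(missing)
    return FeatureTable(table.meta, values, table.design), report


def preprocess_table(
    table: FeatureTable, config: PipelineConfig, seed: int | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Run the full canonical cascade under a pipeline config."""
    report = PreprocessReport()
    table, report = apply_flag_filters(table, report)
    if table.design["is_pooled"].any():
        table = drop_pooled(table)
    table = zeros_to_missing(table)
    table, report = filter_global_observed(table, config.global_observed_min, report)
    table, report = median_normalize(table, report)
    if config.quantile_stage:
        table = quantile_normalize(table)
    table, report = filter_condition_missing(
        table, config.condition_missing_max, config.condition_missing_scope, report
    )
    outliers = detect_outlier_samples(table, config.outlier_z)
    if outliers:
        report.samples_removed.extend(outliers)
        keep = [s for s in table.design.index if s not in set(outliers)]
        table = table.subset_samples(keep)
    table, report = impute_downshifted_normal(
        table,
        config.impute_width,
        config.impute_shift,
        seed=config.seed if seed is None else seed,
        report=report,
    )
    return table, report
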