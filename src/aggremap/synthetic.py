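"""Synthetic quantitative-proteomics experiments and PPI graphs with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: an 11-plex TMT design per timepoint (two treatment groups of five
plus one pooled reference channel), per-feature log2 baselines drawn wide
enough that left-censoring is meaningful, planted log2 fold changes with
balanced signs, Gaussian channel noise, missing-not-at-random left-censoring
plus independent missing-at-random dropout, MaxQuant-style feature flags,
and a planted-partition PPI graph with module-dependent edge confidences.

Every generator is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import FeatureTable, GeneSetCollection, make_design

BASELINE_MEAN = 25.0  # log2-scale centre of MS intensity baselines
BASELINE_SD = 2.0
PEPTIDE_POISSON_MEAN = 3.0  # peptide counts ~ 1 + Poisson(3)


@dataclass
class SyntheticConfig:
    """Parameters of a simulated TMT (or label-free) experiment.

    All proportions lie in [0, 1]; ``lfc_magnitude`` and ``noise_sd`` are in
    log2 units and strictly positive.  ``censor_quantile`` sets the
    per-sample left-censoring threshold (missing-not-at-random), on top of
    which values go missing independently at ``mar_rate``.
    """

    n_features: int = 2000
    n_per_group: int = 5
    de_fraction: float = 0.1
    lfc_magnitude: float = 1.0
    noise_sd: float = 0.25
    censor_quantile: float = 0.05
    mar_rate: float = 0.01
    flag_rates: tuple[float, float, float] = (0.01, 0.01, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_per_group < 1:
            raise ValueError("n_features and n_per_group must be positive")
        for name in ("de_fraction", "censor_quantile", "mar_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not (0 <= r <= 1) for r in self.flag_rates):
            raise ValueError("flag rates must lie in [0, 1]")
        if self.lfc_magnitude <= 0 or self.noise_sd <= 0:
            raise ValueError("lfc_magnitude and noise_sd must be strictly positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-feature fold changes and/or node modules."""

    true_log2fc: pd.Series | None = None
    is_de: pd.Series | None = None
    module_id: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def de_features(self) -> set[str]:
        if self.is_de is None:
            return set()
        return set(self.is_de.index[self.is_de])


class InvalidDesignError(ValueError):
    pass


def generate_design(
    n_per_group: int,
    timepoint_label: str = "day14",
    seed: int = 0,
    *,
    plex_id: str | None = None,
    pooled: bool = True,
) -> pd.DataFrame:
    """Build a TMT plex design: n PFF + n PBS samples plus one pooled channel."""
    if n_per_group < 2:
        raise InvalidDesignError("need at least 2 samples per treatment group")
    plex = plex_id or f"plex_{timepoint_label}"
    ids = [f"PFF_{timepoint_label}_{i + 1}" for i in range(n_per_group)]
    ids += [f"PBS_{timepoint_label}_{i + 1}" for i in range(n_per_group)]
    treatments: list[str | None] = ["PFF"] * n_per_group + ["PBS"] * n_per_group
    flags = [False] * (2 * n_per_group)
    if pooled:
        ids.append(f"POOL_{timepoint_label}")
        treatments.append(None)
        flags.append(True)
    return make_design(ids, treatments, plex_or_run_id=plex, timepoint=timepoint_label, pooled=flags)


def _plant_de(
    rng: np.random.Generator,
    meta: pd.DataFrame,
    config: SyntheticConfig,
    de_candidates: list[str] | None,
    de_signs: dict[str, int] | None,
) -> pd.Series:
    """Choose DE features and signed fold changes (sign-balanced by default).

    Planted effects represent real treatment-responsive proteins, so they
    are never assigned to artifact rows: random planting draws only from
    features that pass the flag and peptide-evidence filters, and an
    explicit ``de_signs`` plan clears the flags (and guarantees peptide
    evidence) of its features via :func:`_assert_quantifiable`.
    """
    feature_ids = meta.index
    true_lfc = pd.Series(0.0, index=feature_ids)
    if de_signs is not None:
        for fid, sign in de_signs.items():
            true_lfc.loc[fid] = np.sign(sign) * config.lfc_magnitude
        return true_lfc
    quantifiable = ~(
        meta["is_reverse"] | meta["is_contaminant"] | meta["only_by_site"]
    )
    if (meta["kind"] == "protein").any():
        quantifiable &= (meta["n_peptides"] > 1) & (meta["n_unique_peptides"] >= 1)
    pool = feature_ids[quantifiable]
    if de_candidates is not None:
        pool = pool.intersection(pd.Index(de_candidates))
    n_de = int(round(config.de_fraction * len(feature_ids)))
    n_de = min(n_de, len(pool))
    chosen = rng.choice(list(pool), size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[: n_de // 2] = -1.0
    rng.shuffle(signs)
    true_lfc.loc[chosen] = signs * config.lfc_magnitude
    return true_lfc


def _assert_quantifiable(meta: pd.DataFrame, feature_ids) -> None:
    """Force explicitly planted features to be real, well-evidenced rows."""
    ids = [f for f in feature_ids if f in meta.index]
    meta.loc[ids, ["is_reverse", "is_contaminant", "only_by_site"]] = False
    meta.loc[ids, "n_peptides"] = meta.loc[ids, "n_peptides"].clip(lower=2)
    meta.loc[ids, "n_unique_peptides"] = meta.loc[ids, "n_unique_peptides"].clip(lower=1)


def _feature_meta(
    rng: np.random.Generator,
    feature_ids: pd.Index,
    leading: pd.Series,
    kind: str,
    flag_rates: tuple[float, float, float],
    site_position: pd.Series | None = None,
) -> pd.DataFrame:
    n = len(feature_ids)
    n_pep = 1 + rng.poisson(PEPTIDE_POISSON_MEAN, size=n)
    n_unique = 1 + rng.binomial(n_pep - 1, 0.5)
    return pd.DataFrame(
        {
            "kind": kind,
            "is_reverse": rng.random(n) < flag_rates[0],
            "is_contaminant": rng.random(n) < flag_rates[1],
            "only_by_site": (rng.random(n) < flag_rates[2]) if kind == "protein" else False,
            "n_peptides": n_pep,
            "n_unique_peptides": n_unique,
            "leading_protein": leading.to_numpy(),
            "site_position": site_position.to_numpy()
            if site_position is not None
            else pd.array([pd.NA] * n, dtype="Int64"),
        },
        index=feature_ids,
    )


def _simulate_matrix(
    rng: np.random.Generator,
    config: SyntheticConfig,
    design: pd.DataFrame,
    true_lfc: pd.Series,
) -> pd.DataFrame:
    """Complete log2 matrix: baseline + group effect + noise; pooled = row mean + noise."""
    n = len(true_lfc)
    analytic = design.index[~design["is_pooled"]]
    pooled = design.index[design["is_pooled"]]
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)

    mat = pd.DataFrame(0.0, index=true_lfc.index, columns=list(design.index))
    for sid in analytic:
        effect = true_lfc.to_numpy() if design.loc[sid, "treatment"] == "PFF" else 0.0
        mat[sid] = baseline + effect + rng.normal(0.0, config.noise_sd, size=n)
    for sid in pooled:
        mat[sid] = mat[analytic].mean(axis=1).to_numpy() + rng.normal(0.0, config.noise_sd, size=n)
    return mat


def _apply_missingness(
    rng: np.random.Generator, mat: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    out = mat.copy()
    if config.censor_quantile > 0:
        for sid in out.columns:
            thr = out[sid].quantile(config.censor_quantile)
            out.loc[out[sid] < thr, sid] = np.nan
    if config.mar_rate > 0:
        mask = rng.random(out.shape) < config.mar_rate
        out = out.mask(mask)
    return out


def generate_tmt_experiment(
    config: SyntheticConfig,
    design: pd.DataFrame,
    *,
    feature_symbols: list[str] | None = None,
    de_candidates: list[str] | None = None,
    de_signs: dict[str, int] | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a TMT protein-group table with planted fold changes.

    ``feature_symbols`` optionally names the features (uppercase gene
    symbols); ``de_candidates`` restricts which features may be DE, and
    ``de_signs`` (feature -> +1/-1) plants an exact signed DE assignment.
    """
    rng = np.random.default_rng(config.seed)
    if feature_symbols is not None:
        if len(feature_symbols) != config.n_features:
            raise ValueError("feature_symbols length must equal n_features")
        ids = pd.Index([s.upper() for s in feature_symbols], name="feature_id")
    else:
        ids = pd.Index([f"P{i:05d}" for i in range(config.n_features)], name="feature_id")

    meta = _feature_meta(rng, ids, pd.Series(ids, index=ids), "protein", config.flag_rates)
    true_lfc = _plant_de(rng, meta, config, de_candidates, de_signs)
    if de_signs is not None:
        _assert_quantifiable(meta, list(de_signs))
    mat = _simulate_matrix(rng, config, design, true_lfc)
    mat = _apply_missingness(rng, mat, config)

    truth = SyntheticTruth(true_log2fc=true_lfc, is_de=true_lfc.ne(0.0))
    return FeatureTable(meta, mat, design), truth


def generate_phospho_experiment(
    config: SyntheticConfig,
    design: pd.DataFrame,
    *,
    sites_per_protein: int = 3,
    protein_symbols: list[str] | None = None,
    de_candidates: list[str] | None = None,
    de_signs: dict[str, int] | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a phosphosite table; several sites share one leading protein.

    ``n_features`` counts sites.  Site ids are ``<PROTEIN>_<position>``.
    ``de_candidates``/``de_signs`` refer to site ids.
    """
    rng = np.random.default_rng(config.seed)
    n_prot = int(np.ceil(config.n_features / sites_per_protein))
    if protein_symbols is not None:
        if len(protein_symbols) < n_prot:
            raise ValueError(f"need at least {n_prot} protein symbols")
        prots = [s.upper() for s in protein_symbols[:n_prot]]
    else:
        prots = [f"PH{i:05d}" for i in range(n_prot)]

    leading, positions = [], []
    for p in prots:
        for k in range(sites_per_protein):
            if len(leading) == config.n_features:
                break
            leading.append(p)
            positions.append(17 + 10 * k)  # arbitrary, distinct per protein
    ids = pd.Index([f"{p}_{pos}" for p, pos in zip(leading, positions)], name="feature_id")
    leading_s = pd.Series(leading, index=ids)
    pos_s = pd.Series(pd.array(positions, dtype="Int64"), index=ids)

    meta = _feature_meta(rng, ids, leading_s, "phosphosite", config.flag_rates, pos_s)
    true_lfc = _plant_de(rng, meta, config, de_candidates, de_signs)
    if de_signs is not None:
        _assert_quantifiable(meta, list(de_signs))
    mat = _simulate_matrix(rng, config, design, true_lfc)
    mat = _apply_missingness(rng, mat, config)

    truth = SyntheticTruth(true_log2fc=true_lfc, is_de=true_lfc.ne(0.0))
    return FeatureTable(meta, mat, design), truth


def generate_insoluble_lfq(
    config: SyntheticConfig,
    design_no_pool: pd.DataFrame,
    loading_scales: list[float],
    *,
    feature_symbols: list[str] | None = None,
    de_candidates: list[str] | None = None,
    de_signs: dict[str, int] | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a label-free insoluble-fraction run with per-sample loading shifts.

    Each sample's log2 intensities are shifted by log2(loading_scale) to
    emulate differences in peptide amount loaded.
    """
    if design_no_pool["is_pooled"].any():
        raise ValueError("label-free design must not contain a pooled channel")
    scales = np.asarray(loading_scales, dtype=float)
    if len(scales) != len(design_no_pool):
        raise ValueError("one loading scale per sample required")
    if (scales <= 0).any():
        raise ValueError("loading scales must be strictly positive")

    design = design_no_pool.copy()
    design["loading_scale"] = scales
    table, truth = generate_tmt_experiment(
        config,
        design,
        feature_symbols=feature_symbols,
        de_candidates=de_candidates,
        de_signs=de_signs,
    )
    shifted = table.values.add(np.log2(scales), axis=1)
    return FeatureTable(table.meta, shifted, design), truth


# ---------------------------------------------------------------------------
# PPI graphs and gene sets


class SeparationError(ValueError):
    pass


def generate_ppi_network(
    n_nodes: int,
    n_modules: int,
    p_within: float,
    p_between: float,
    conf_within: float,
    conf_between: float,
    seed: int = 0,
    *,
    conf_sd: float = 0.0002,
    node_names: list[str] | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition PPI graph with module-dependent edge confidences.

    Intra-module pairs are joined with probability ``p_within`` and given a
    confidence drawn from Normal(conf_within, conf_sd) clipped to [0, 1];
    inter-module pairs use ``p_between``/``conf_between``.
    """
    if not p_within > p_between:
        raise SeparationError("p_within must exceed p_between")
    for name, v in (("conf_within", conf_within), ("conf_between", conf_between)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    if node_names is not None:
        if len(node_names) != n_nodes:
            raise ValueError("node_names length must equal n_nodes")
        names = [n.upper() for n in node_names]
    else:
        names = [f"G{i:04d}" for i in range(n_nodes)]

    module_of = np.array([i % n_modules for i in range(n_nodes)])
    module_of.sort()

    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = module_of[i] == module_of[j]
            p = p_within if same else p_between
            if rng.random() < p:
                centre = conf_within if same else conf_between
                conf = float(np.clip(rng.normal(centre, conf_sd), 0.0, 1.0))
                graph.add_edge(names[i], names[j], confidence=conf)

    truth = SyntheticTruth(
        module_id=pd.Series(module_of, index=pd.Index(names, name="node"), name="module_id")
    )
    return graph, truth


def generate_gene_sets(
    network_truth: SyntheticTruth,
    n_extra_sets: int = 5,
    seed: int = 0,
) -> GeneSetCollection:
    """One gene set per planted module plus random same-sized decoy sets."""
    if network_truth.module_id is None:
        raise ValueError("network truth carries no module labels")
    modules = network_truth.module_id
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    sizes = []
    for mid in sorted(modules.unique()):
        members = set(modules.index[modules == mid])
        sets[f"module_{mid:02d}"] = members
        sizes.append(len(members))
    nodes = list(modules.index)
    for k in range(n_extra_sets):
        size = int(rng.choice(sizes))
        sets[f"decoy_{k:02d}"] = set(rng.choice(nodes, size=size, replace=False))
    return GeneSetCollection(sets, provenance="synthetic")
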