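"""Readers and writers for the tabular formats the pipeline touches.

Supported formats: MaxQuant-dialect protein-group and phosphosite TSVs
(``Reporter intensity corrected <n>`` / ``LFQ intensity <sample>`` columns,
"+"-marked flag columns), 3-column PPI edge tables, GMT gene-set files,
design TSVs, and a native TSV trio (values / meta / design) that round-trips
a :class:`~aggremap.datatypes.FeatureTable` exactly.

Gene symbols are uppercased at every ingestion point so that mouse-derived
tables join cleanly against human-centric PPI resources; raw intensities are
log2-transformed at read time (zeros are preserved as zero and only turned
into missing values by the preprocessing cascade).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig, load_config  # noqa: F401  (re-exported)
from .datatypes import DESIGN_COLUMNS, META_COLUMNS, FeatureTable, GeneSetCollection

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

DEFAULT_COLUMN_MAP = {
    "protein_ids": "Majority protein IDs",
    "gene_names": "Gene names",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
    "peptides": "Peptides",
    "unique_peptides": "Unique peptides",
    "position": "Position",
    "multiplicity": "Multiplicity",
}


class FormatError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


def _require_columns(df: pd.DataFrame, names: list[str], path: Path) -> None:
    for name in names:
        if name not in df.columns:
            raise FormatError(f"{path}: required column {name!r} is missing")


def _flag_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        return np.zeros(len(df), dtype=bool)
    return df[name].fillna("").astype(str).str.strip().eq("+").to_numpy()


def _int_column(df: pd.DataFrame, name: str, default: int) -> np.ndarray:
    if name not in df.columns:
        return np.full(len(df), default, dtype=int)
    return (
        pd.to_numeric(df[name], errors="coerce").fillna(default).astype(int).to_numpy()
    )


def _parse_intensities(df: pd.DataFrame, channel_columns: list[str], path: Path) -> np.ndarray:
    raw = df[channel_columns]
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna().to_numpy() & raw.notna().to_numpy()
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise FormatError(f"{path}: non-numeric intensity at data row {row}")
    values = parsed.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logged = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)), values)
    return logged


def _symbol(raw: str) -> str:
    return str(raw).split(";")[0].strip().upper()


def read_protein_groups(
    path: str | Path,
    channel_columns: list[str],
    design: pd.DataFrame,
    column_map: dict[str, str] | None = None,
) -> FeatureTable:
    """Read a MaxQuant-style proteinGroups TSV into a FeatureTable.

    ``channel_columns`` name the intensity columns in design order.  Raw
    intensities are log2-transformed; raw zeros stay zero (they become
    missing later, in preprocessing).  "+"-marked flag columns map to
    booleans.  Row order is preserved.
    """
    path = Path(path)
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, [cmap["protein_ids"], *channel_columns], path)
    if len(channel_columns) != len(design):
        raise FormatError(
            f"{path}: {len(channel_columns)} channel columns for {len(design)} design samples"
        )

    logged = _parse_intensities(df, channel_columns, path)
    gene_col = cmap["gene_names"] if cmap["gene_names"] in df.columns else cmap["protein_ids"]
    leading = df[gene_col].fillna(df[cmap["protein_ids"]]).map(_symbol)
    ids = df[cmap["protein_ids"]].map(_symbol)
    ids = _dedupe_ids(list(ids))

    meta = pd.DataFrame(
        {
            "kind": "protein",
            "is_reverse": _flag_column(df, cmap["reverse"]),
            "is_contaminant": _flag_column(df, cmap["contaminant"]),
            "only_by_site": _flag_column(df, cmap["only_by_site"]),
            "n_peptides": _int_column(df, cmap["peptides"], 0),
            "n_unique_peptides": _int_column(df, cmap["unique_peptides"], 0),
            "leading_protein": leading.to_numpy(),
            "site_position": pd.array([pd.NA] * len(df), dtype="Int64"),
        },
        index=pd.Index(ids, name="feature_id"),
    )
    values = pd.DataFrame(logged, index=meta.index, columns=list(design.index))
    return FeatureTable(meta, values, design)


def _dedupe_ids(ids: list[str]) -> list[str]:
    """Disambiguate duplicate feature ids with a stable numeric suffix."""
    seen: dict[str, int] = {}
    out = []
    for fid in ids:
        if fid in seen:
            seen[fid] += 1
            logger.warning("duplicate feature id %s disambiguated", fid)
            out.append(f"{fid}.{seen[fid]}")
        else:
            seen[fid] = 0
            out.append(fid)
    return out


def read_phospho_sites(
    path: str | Path,
    channel_columns: list[str],
    design: pd.DataFrame,
    column_map: dict[str, str] | None = None,
) -> FeatureTable:
    """Read a MaxQuant-style phosphosite TSV.

    The feature id is composed as ``LEADINGPROTEIN_<position>`` with a
    ``_Mx`` multiplicity suffix when a multiplicity column is present;
    duplicates are disambiguated with a stable numeric suffix.
    """
    path = Path(path)
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, [cmap["protein_ids"], cmap["position"], *channel_columns], path)
    if len(channel_columns) != len(design):
        raise FormatError(
            f"{path}: {len(channel_columns)} channel columns for {len(design)} design samples"
        )

    logged = _parse_intensities(df, channel_columns, path)
    gene_col = cmap["gene_names"] if cmap["gene_names"] in df.columns else cmap["protein_ids"]
    leading = df[gene_col].fillna(df[cmap["protein_ids"]]).map(_symbol)
    position = pd.to_numeric(df[cmap["position"]], errors="coerce").astype("Int64")
    if position.isna().any():
        row = int(position.isna().to_numpy().argmax())
        raise FormatError(f"{path}: unparsable site position at data row {row}")

    ids = [f"{g}_{p}" for g, p in zip(leading, position)]
    if cmap["multiplicity"] in df.columns:
        mult = df[cmap["multiplicity"]].fillna("")
        ids = [f"{i}_M{m}" if str(m).strip() else i for i, m in zip(ids, mult)]
    ids = _dedupe_ids(ids)

    meta = pd.DataFrame(
        {
            "kind": "phosphosite",
            "is_reverse": _flag_column(df, cmap["reverse"]),
            "is_contaminant": _flag_column(df, cmap["contaminant"]),
            "only_by_site": False,
            "n_peptides": _int_column(df, cmap["peptides"], 1),
            "n_unique_peptides": _int_column(df, cmap["unique_peptides"], 1),
            "leading_protein": leading.to_numpy(),
            "site_position": position.to_numpy(),
        },
        index=pd.Index(ids, name="feature_id"),
    )
    values = pd.DataFrame(logged, index=meta.index, columns=list(design.index))
    return FeatureTable(meta, values, design)


# ---------------------------------------------------------------------------
# PPI edge tables


def read_edge_table(path: str | Path) -> nx.Graph:
    """Read a 3-column (node_a, node_b, confidence) TSV into an undirected graph.

    Symbols are uppercased, self-loops dropped, and duplicate edges keep
    the maximum confidence.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    _require_columns(df, ["node_a", "node_b", "confidence"], path)
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any():
        raise FormatError(f"{path}: non-numeric confidence value")
    if ((conf < 0) | (conf > 1)).any():
        raise FormatError(f"{path}: confidence outside [0, 1]")

    graph = nx.Graph()
    for a, b, c in zip(df["node_a"], df["node_b"], conf):
        a, b = str(a).upper(), str(b).upper()
        if a == b:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], float(c))
        else:
            graph.add_edge(a, b, confidence=float(c))
    return graph


def write_edge_table(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), float(d["confidence"])) for a, b, d in graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, members...)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise FormatError(f"{path}:{line_no}: gene set with empty member list")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
        sets[name] = {p.strip().upper() for p in parts[2:] if p.strip()}
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.provenance or "na", *sorted(members)])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Native FeatureTable round-trip (values / meta / design TSV trio)


def write_feature_table(table: FeatureTable, prefix: str | Path) -> list[Path]:
    """Write a FeatureTable as <prefix>_{values,meta,design}.tsv (log2 scale)."""
    prefix = Path(prefix)
    paths = [
        prefix.with_name(prefix.name + "_values.tsv"),
        prefix.with_name(prefix.name + "_meta.tsv"),
        prefix.with_name(prefix.name + "_design.tsv"),
    ]
    table.values.to_csv(paths[0], sep="\t", float_format=_FLOAT_FMT)
    table.meta.to_csv(paths[1], sep="\t")
    table.design.to_csv(paths[2], sep="\t", float_format=_FLOAT_FMT)
    return paths


def read_feature_table(prefix: str | Path) -> FeatureTable:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_name(prefix.name + "_values.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(prefix.with_name(prefix.name + "_meta.tsv"), sep="\t", index_col=0)
    design = pd.read_csv(prefix.with_name(prefix.name + "_design.tsv"), sep="\t", index_col=0)
    meta = meta.reindex(columns=META_COLUMNS)
    for col in ("is_reverse", "is_contaminant", "only_by_site"):
        meta[col] = meta[col].astype(bool)
    meta["site_position"] = pd.to_numeric(meta["site_position"], errors="coerce").astype("Int64")
    design = design.reindex(columns=DESIGN_COLUMNS)
    design["is_pooled"] = design["is_pooled"].astype(bool)
    design.index = design.index.astype(str)
    values.columns = values.columns.astype(str)
    return FeatureTable(meta, values, design)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write differential-abundance results (feature_id, log2fc, t, df, p, padj, call)."""
    cols = [c for c in ["log2fc", "t_mod", "df_total", "p", "padj", "call"] if c in results]
    results[cols].to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="feature_id")


def write_seed_list(members: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(members)) + ("\n" if members else ""))


def read_seed_list(path: str | Path) -> set[str]:
    return {
        line.strip().upper() for line in Path(path).read_text().splitlines() if line.strip()
    }
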