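"""Exact hypergeometric over-representation and curated-list overlap.

Given a query list of genes, a gene-set collection and a background
universe, each set is scored with the one-sided hypergeometric upper tail
P[X >= k] (the observed overlap is included), BH-adjusted across the
collection.  The universe defaults to the features surviving preprocessing
(the quantified background), guarding against detection-bias inflation.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection, SeedList
from .diffabund import bh_adjust
from .network import ModulePartition, NetworkResult, zero_order_network


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_ora(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` against every set in ``collection``.

    Query and sets are intersected with the universe before testing.
    Returns one row per set (set_name, k, K, n, N, enrichment_ratio, p,
    padj), sorted by p then name.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    q = {str(g).upper() for g in query} & universe
    N, n = len(universe), len(q)

    rows = []
    for name, members in collection.sets.items():
        s = members & universe
        K = len(s)
        k = len(q & s)
        p = hypergeometric_tail(k, N, K, n)
        ratio = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
        rows.append((name, k, K, n, N, ratio, p))
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "enrichment_ratio", "p"]
    )
    out["padj"] = bh_adjust(out["p"]) if len(out) else []
    return out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


def geneset_overlap(
    seed_up: SeedList | set[str],
    seed_down: SeedList | set[str],
    curated: set[str],
) -> tuple[set[str], set[str]]:
    """Intersect up/down seed lists with a curated gene list (e.g. RBPs)."""
    up = seed_up.members if isinstance(seed_up, SeedList) else set(seed_up)
    down = seed_down.members if isinstance(seed_down, SeedList) else set(seed_down)
    cur = {str(g).upper() for g in curated}
    return ({str(g).upper() for g in up} & cur, {str(g).upper() for g in down} & cur)


def extract_overlap_subnetwork(
    graph: nx.Graph, overlap: set[str], min_conf: float = 0.0
) -> NetworkResult:
    """Induced subnetwork on an overlap gene set (zero-order construction)."""
    if not overlap:
        return NetworkResult(graph=nx.Graph(), unmapped_seeds=set())
    return zero_order_network(graph, overlap, min_conf)


def annotate_modules(
    partition: ModulePartition,
    collection: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Per-module ORA against the collection; the network nodes are the universe.

    Returns one row per (module, set) with the module's rank-1 annotation
    marked; modules with fewer than 2 members are annotated but flagged
    low-power.
    """
    frames = []
    for mid, members in sorted(partition.modules().items()):
        ora = hypergeometric_ora(members, collection, universe)
        ora.insert(0, "module_id", mid)
        ora["module_size"] = len(members)
        ora["low_power"] = len(members) < 2
        ora["top_hit"] = False
        if len(ora):
            ora.loc[0, "top_hit"] = True
        frames.append(ora)
    if not frames:
        return pd.DataFrame(
            columns=[
                "module_id", "set_name", "k", "K", "n", "N",
                "enrichment_ratio", "p", "padj", "module_size", "low_power", "top_hit",
            ]
        )
    return pd.concat(frames, ignore_index=True)
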