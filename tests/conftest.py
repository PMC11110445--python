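import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aggremap.datatypes import FeatureTable, make_design


def small_design(n_per_group=5, pooled=True, timepoint="day14"):
    ids = [f"PFF_{i}" for i in range(n_per_group)] + [f"PBS_{i}" for i in range(n_per_group)]
    treatments = ["PFF"] * n_per_group + ["PBS"] * n_per_group
    flags = [False] * (2 * n_per_group)
    if pooled:
        ids.append("POOL")
        treatments.append(None)
        flags.append(True)
    return make_design(ids, treatments, timepoint=timepoint, pooled=flags)


def make_table(values, design, *, kind="protein", leading=None, flags=None, peptides=None):
    """Hand-build a FeatureTable from a features x samples array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = pd.Index([f"F{i:03d}" for i in range(n)], name="feature_id")
    meta = pd.DataFrame(
        {
            "kind": kind,
            "is_reverse": False,
            "is_contaminant": False,
            "only_by_site": False,
            "n_peptides": 5,
            "n_unique_peptides": 2,
            "leading_protein": leading if leading is not None else list(ids),
            "site_position": pd.array([pd.NA] * n, dtype="Int64"),
        },
        index=ids,
    )
    if flags is not None:
        for col, vals in flags.items():
            meta[col] = vals
    if peptides is not None:
        meta["n_peptides"], meta["n_unique_peptides"] = peptides
    vals = pd.DataFrame(values, index=ids, columns=list(design.index))
    return FeatureTable(meta, vals, design)


@pytest.fixture
def design_5v5():
    return small_design(5)


@pytest.fixture
def design_no_pool():
    return small_design(5, pooled=False)


def random_weighted_graph(n_nodes, p_edge, rng):
    """Erdos-Renyi graph with uniform edge confidences, for oracle tests."""
    g = nx.Graph()
    names = [f"N{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(names[i], names[j], confidence=float(rng.random()))
    return g
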