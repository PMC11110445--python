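"""Seed-driven PPI network construction and module detection.

Networks are undirected simple :class:`networkx.Graph` objects whose nodes
are uppercase gene symbols and whose edges carry a ``confidence`` attribute
in [0, 1].  Seed lists of differential proteins drive two constructions: the
zero-order network (induced subgraph on the seeds themselves) and the
first-order network (seeds plus their direct neighbors).  Confidence
filtering uses ``>=`` semantics so that a cutoff of 0.999 retains edges
scored exactly 0.999.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity

from .datatypes import SeedList


@dataclass
class NetworkResult:
    """A constructed subnetwork plus the seeds that could not be mapped."""

    graph: nx.Graph
    unmapped_seeds: set[str] = field(default_factory=set)


@dataclass
class ModulePartition:
    """Node -> module assignment with the partition's modularity."""

    membership: pd.Series
    modularity: float

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mid in self.membership.items():
            out.setdefault(int(mid), set()).add(node)
        return out


def filter_by_confidence(graph: nx.Graph, min_conf: float) -> nx.Graph:
    """Keep edges with confidence >= min_conf; isolated nodes are retained."""
    if not (0 <= min_conf <= 1):
        raise ValueError("min_conf must lie in [0, 1]")
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(
        (a, b, d) for a, b, d in graph.edges(data=True) if d["confidence"] >= min_conf
    )
    return out


def _normalize_seeds(seeds: SeedList | set[str]) -> set[str]:
    members = seeds.members if isinstance(seeds, SeedList) else set(seeds)
    if not members:
        raise ValueError("seed list is empty")
    return {str(s).upper() for s in members}


def zero_order_network(
    graph: nx.Graph, seeds: SeedList | set[str], min_conf: float = 0.0
) -> NetworkResult:
    """Induced subgraph on the seed symbols present in the network.

    Seeds absent from the network are reported as unmapped, never silently
    dropped; found-but-isolated seeds stay as isolated nodes.
    """
    members = _normalize_seeds(seeds)
    filtered = filter_by_confidence(graph, min_conf)
    found = members & set(filtered.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(found))
    sub.add_edges_from(
        (a, b, d)
        for a, b, d in filtered.edges(data=True)
        if a in found and b in found
    )
    return NetworkResult(graph=sub, unmapped_seeds=members - found)


def first_order_network(
    graph: nx.Graph,
    seeds: SeedList | set[str],
    min_conf: float = 0.0,
    mode: str = "induced",
) -> NetworkResult:
    """Seeds plus their direct neighbors after confidence filtering.

    mode='induced' (default) keeps every filtered edge among seeds and
    neighbors, including neighbor-neighbor edges; mode='seed_incident'
    keeps only edges touching a seed.
    """
    if mode not in ("induced", "seed_incident"):
        raise ValueError("mode must be 'induced' or 'seed_incident'")
    members = _normalize_seeds(seeds)
    filtered = filter_by_confidence(graph, min_conf)
    found = members & set(filtered.nodes)
    neighbors: set[str] = set()
    for s in found:
        neighbors.update(filtered.neighbors(s))
    node_set = found | neighbors

    sub = nx.Graph()
    sub.add_nodes_from(sorted(node_set))
    for a, b, d in filtered.edges(data=True):
        if a in node_set and b in node_set:
            if mode == "seed_incident" and a not in found and b not in found:
                continue
            sub.add_edge(a, b, **d)
    return NetworkResult(graph=sub, unmapped_seeds=members - found)


def intersect_node_sets(*networks: nx.Graph | NetworkResult) -> set[str]:
    """Common node symbols across two or more networks."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to intersect")
    sets = [
        set((n.graph if isinstance(n, NetworkResult) else n).nodes) for n in networks
    ]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def detect_modules(graph: nx.Graph, seed: int = 0) -> ModulePartition:
    """Greedy modularity-maximization community partition, deterministic.

    Module ids are assigned in decreasing community-size order (ties broken
    by smallest member symbol); isolated nodes become singleton modules.
    An edgeless network yields the all-singleton partition with
    modularity 0.
    """
    nodes = sorted(graph.nodes)
    if graph.number_of_edges() == 0:
        membership = pd.Series(range(len(nodes)), index=nodes, dtype=int, name="module_id")
        return ModulePartition(membership=membership, modularity=0.0)

    communities = [set(c) for c in greedy_modularity_communities(graph)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    membership = pd.Series(index=pd.Index(nodes, name="node"), dtype=int, name="module_id")
    for mid, comm in enumerate(communities):
        for node in comm:
            membership.loc[node] = mid
    q = modularity(graph, communities)
    return ModulePartition(membership=membership.astype(int), modularity=float(q))


def write_partition(partition: ModulePartition, path) -> None:
    partition.membership.rename("module_id").to_csv(path, sep="\t", index_label="node")
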