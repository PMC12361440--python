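"""Community detection and partition/centrality statistics for interomics networks.

Louvain modularity maximization (greedy multi-level node aggregation) splits
each network into communities at a configurable resolution; partition quality
is summarized by modularity (at the standard gamma = 1), coverage (fraction of
edges inside communities) and performance (fraction of node pairs classified
correctly: intra-pairs that are edges plus inter-pairs that are non-edges).
Closeness centrality uses the reachable-count scaling for disconnected graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """A disjoint cover of the network's nodes.

    Communities are stored sorted (largest first, ties by smallest node id)
    so that identical partitions serialize identically.
    """

    communities: list[frozenset]
    resolution: float
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set = set()
        for comm in self.communities:
            if seen & comm:
                raise ValueError("communities must be disjoint")
            seen |= comm
        self.communities = sorted(
            (frozenset(c) for c in self.communities),
            key=lambda c: (-len(c), min(c) if c else ""),
        )

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def membership(self) -> dict:
        return {node: i for i, comm in enumerate(self.communities) for node in comm}

    def covers(self, G: nx.Graph) -> bool:
        return set().union(*self.communities) == set(G.nodes) if self.communities else not G.nodes


@dataclass
class PartitionQuality:
    modularity: float
    coverage: float
    performance: float
    n_communities: int

    def to_dict(self) -> dict:
        return {
            "modularity": self.modularity,
            "coverage": self.coverage,
            "performance": self.performance,
            "n_communities": self.n_communities,
        }


def louvain_partition(G: nx.Graph, resolution: float = 0.45, seed: int = 0) -> Partition:
    """Louvain community detection on the unweighted graph.

    Correlation signs stay edge attributes only; the aggregation treats every
    edge with weight 1. Deterministic for a fixed seed.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    comms = nx.community.louvain_communities(
        G, weight=None, resolution=resolution, seed=seed
    )
    return Partition([frozenset(c) for c in comms], resolution=resolution, seed=seed)


def partition_quality(partition: Partition, G: nx.Graph) -> PartitionQuality:
    """Modularity (gamma = 1), coverage and performance of a partition.

    A zero-edge network has undefined modularity (NaN, logged); coverage and
    performance are still defined through absent pairs.
    """
    if not partition.covers(G):
        raise ValueError("partition does not cover the network's nodes")
    communities = [set(c) for c in partition.communities]
    if G.number_of_edges() == 0:
        logger.warning("zero-edge network: modularity undefined")
        modularity = float("nan")
        coverage = 1.0
        n = G.number_of_nodes()
        if n < 2:
            performance = 1.0
        else:
            intra_pairs = sum(len(c) * (len(c) - 1) // 2 for c in communities)
            total_pairs = n * (n - 1) // 2
            performance = (total_pairs - intra_pairs) / total_pairs
    else:
        modularity = float(nx.community.modularity(G, communities, weight=None))
        coverage, performance = nx.community.partition_quality(G, communities)
    return PartitionQuality(
        modularity=modularity,
        coverage=float(coverage),
        performance=float(performance),
        n_communities=partition.n_communities,
    )


def closeness(G: nx.Graph) -> dict:
    """Closeness centrality per node, scaled for disconnected graphs.

    C(v) = ((r - 1) / sum of distances to reachable nodes) * ((r - 1) / (n - 1))
    where r counts reachable nodes; isolated nodes get 0.
    """
    return nx.closeness_centrality(G)


def jaccard_similarity(nodes_a: set, nodes_b: set) -> float:
    """|A intersect B| / |A union B|; two empty sets give 0 by convention."""
    nodes_a, nodes_b = set(nodes_a), set(nodes_b)
    union = nodes_a | nodes_b
    if not union:
        logger.info("jaccard of two empty sets reported as 0 by convention")
        return 0.0
    return len(nodes_a & nodes_b) / len(union)


def community_connectivity(
    partition: Partition, G: nx.Graph
) -> tuple[pd.DataFrame, dict]:
    """Size, average shortest path and average clustering per community.

    The shortest-path average is computed on each community's induced
    subgraph; a disconnected subgraph falls back to its largest connected
    component (flagged). Singleton communities have no defined path length
    and are excluded from the across-community means (logged).
    Returns the per-community table and summary means +/- sd.
    """
    rows = []
    for i, comm in enumerate(partition.communities):
        sub = G.subgraph(comm)
        size = len(comm)
        flag = ""
        if size == 1:
            avg_path = float("nan")
            flag = "singleton: path undefined"
            logger.info("community %d is a singleton; excluded from path means", i)
        elif nx.is_connected(sub):
            avg_path = float(nx.average_shortest_path_length(sub))
        else:
            giant = max(nx.connected_components(sub), key=len)
            avg_path = float(nx.average_shortest_path_length(sub.subgraph(giant)))
            flag = f"disconnected: path on largest component ({len(giant)}/{size})"
        avg_clust = float(nx.average_clustering(sub)) if size > 0 else float("nan")
        rows.append(
            dict(community=i, size=size, avg_shortest_path=avg_path,
                 avg_clustering=avg_clust, flag=flag)
        )
    table = pd.DataFrame(rows)
    paths = table["avg_shortest_path"].dropna()
    summary = {
        "mean_size": float(table["size"].mean()),
        "sd_size": float(table["size"].std(ddof=1)) if len(table) > 1 else 0.0,
        "mean_avg_shortest_path": float(paths.mean()) if len(paths) else float("nan"),
        "sd_avg_shortest_path": float(paths.std(ddof=1)) if len(paths) > 1 else 0.0,
        "mean_avg_clustering": float(table["avg_clustering"].mean()),
        "sd_avg_clustering": float(table["avg_clustering"].std(ddof=1)) if len(table) > 1 else 0.0,
    }
    return table, summary
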