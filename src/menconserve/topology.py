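"""Overall and per-node topological indices of co-occurrence networks.

All indices are computed on the simple unweighted graph; correlation signs
stay on the edges as annotations only. Node connectivity (degree) is the
core node property: per network it is ranked (rank 1 = most connected,
ties get average ranks) and normalized onto [1, 100] by

    rank_norm_i = (1 - (Max - rank_org_i) / (Max - 1)) * 99 + 1

with Max the maximum rank in that network, so the hub maps to 1 and the
least-connected node to 100. The connectivity score is 101 - rank_norm
(zero when a node is absent from a network), putting hubs at 100 on a
0-100 scale comparable across networks of different sizes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import CorrelationNetwork

__all__ = [
    "UndefinedMetricError",
    "TopologySummary",
    "node_connectivity",
    "average_geodesic_distance",
    "average_clustering_coefficient",
    "greedy_modularity",
    "normalize_connectivity_ranks",
    "connectivity_scores",
    "summarize_topology",
    "node_profiles",
    "OVERALL_INDICES",
]


class UndefinedMetricError(ValueError):
    """A topological index is undefined for this network (e.g. no edges)."""


@dataclasses.dataclass(frozen=True)
class TopologySummary:
    """Overall indices of one network."""

    layer: str
    group: str
    n_nodes: int
    n_edges: int
    avg_gd: float
    avg_cc: float
    modularity: float


def node_connectivity(net: CorrelationNetwork) -> dict[str, int]:
    """Unweighted degree of every node."""
    return {n: d for n, d in net.graph.degree()}


def average_geodesic_distance(net: CorrelationNetwork) -> float:
    """Mean shortest-path length over mutually reachable node pairs.

    Pairs in different components are excluded, so the index stays defined
    on the disconnected networks thresholding routinely produces.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("average geodesic distance needs at least one edge")
    total = 0
    count = 0
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        sub = g.subgraph(component)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            count += len(lengths) - 1  # drop the zero self-distance
    return total / count


def average_clustering_coefficient(net: CorrelationNetwork) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    if net.graph.number_of_nodes() == 0:
        return 0.0
    return nx.average_clustering(net.graph)


def greedy_modularity(net: CorrelationNetwork) -> tuple[dict[str, int], float]:
    """Greedy agglomerative modularity maximization (Clauset–Newman–Moore).

    Returns the partition (node -> module index) and its Newman–Girvan
    modularity Q on the unweighted graph.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("modularity needs at least one edge")
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight=None)
    partition = {node: k for k, comm in enumerate(communities) for node in comm}
    q = nx.algorithms.community.modularity(g, communities, weight=None)
    return partition, q


def normalize_connectivity_ranks(connectivity: Mapping[str, int]) -> dict[str, float]:
    """Rank connectivities (1 = most connected, average ties) onto [1, 100]."""
    nodes = list(connectivity)
    if len(nodes) < 2:
        raise ValueError("rank normalization needs at least 2 nodes")
    degrees = np.array([connectivity[n] for n in nodes], dtype=float)
    ranks = stats.rankdata(-degrees, method="average")
    max_rank = ranks.max()
    norm = (1.0 - (max_rank - ranks) / (max_rank - 1.0)) * 99.0 + 1.0
    return {n: float(v) for n, v in zip(nodes, norm)}


def connectivity_scores(
    rank_norms: Mapping[str, Mapping[str, float]],
    node_universe: Iterable[str],
    networks: Sequence[str],
) -> pd.DataFrame:
    """Node-by-network connectivity scores: 101 - rank_norm, 0 when absent."""
    nodes = list(node_universe)
    scores = pd.DataFrame(0.0, index=nodes, columns=list(networks))
    for net_id in networks:
        for node, rn in rank_norms.get(net_id, {}).items():
            if node in scores.index:
                scores.loc[node, net_id] = 101.0 - rn
    return scores


def summarize_topology(net: CorrelationNetwork) -> TopologySummary:
    """All overall indices of one network."""
    _, q = greedy_modularity(net)
    return TopologySummary(
        layer=net.layer,
        group=net.group,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        avg_gd=average_geodesic_distance(net),
        avg_cc=average_clustering_coefficient(net),
        modularity=q,
    )


#: Named overall indices usable in null-model comparisons.
OVERALL_INDICES = {
    "avg_gd": average_geodesic_distance,
    "avg_cc": average_clustering_coefficient,
    "modularity": lambda net: greedy_modularity(net)[1],
    "n_nodes": lambda net: net.n_nodes,
    "n_edges": lambda net: net.n_edges,
}


def node_profiles(networks: Sequence[CorrelationNetwork]) -> pd.DataFrame:
    """Long-format per-node profile across networks.

    Columns: node, layer, group, connectivity, rank_norm, score.
    """
    rows = []
    for net in networks:
        conn = node_connectivity(net)
        if len(conn) < 2:
            continue
        rank_norm = normalize_connectivity_ranks(conn)
        for node in conn:
            rows.append(
                {
                    "node": node,
                    "layer": net.layer,
                    "group": net.group,
                    "connectivity": conn[node],
                    "rank_norm": rank_norm[node],
                    "score": 101.0 - rank_norm[node],
                }
            )
    return pd.DataFrame(rows)
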