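"""The three network measures: clustering, path length, modularity.

All three are computed on the unweighted (binarised) graph by default —
path length is defined in steps (edges), and using one convention keeps the
measures commensurate.  Weighted variants are available behind a flag for
sensitivity analysis.

Modularity is the Newman–Girvan Q of the best partition found by Louvain
community detection over a number of seeded restarts; Louvain is
order-dependent, so restarts stabilise Q while keeping the result
reproducible for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

__all__ = [
    "NetworkMetrics",
    "clustering_coefficient",
    "average_shortest_path_length",
    "partition_modularity",
    "modularity_q",
    "compute_metrics",
]


@dataclass
class NetworkMetrics:
    """Summary of one network: CC, ASPL, Q and the community count."""

    cc: float
    aspl: float
    q: float
    n_communities: int
    n_nodes: int
    n_edges: int

    def to_report(self, group: str, seed: int) -> dict:
        return {
            "group": group,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "cc": self.cc,
            "aspl": self.aspl,
            "q": self.q,
            "n_communities": self.n_communities,
            "seed": seed,
        }


def clustering_coefficient(net: nx.Graph, weighted: bool = False) -> float:
    """Mean local clustering coefficient (Watts–Strogatz).

    A node's local CC is the fraction of its neighbour pairs that are
    themselves connected; nodes of degree < 2 contribute 0.  The weighted
    variant is the geometric-mean edge-intensity generalisation.
    """
    return float(nx.average_clustering(net, weight="weight" if weighted else None))


def _inv_weight(u, v, d) -> float:
    return 1.0 / d["weight"]


def average_shortest_path_length(net: nx.Graph, weighted: bool = False) -> float:
    """Mean shortest-path length in hops over all unordered node pairs.

    The weighted variant uses distance 1/weight so strong associations act
    as short links.  Disconnected input raises ``ValueError``.
    """
    if not nx.is_connected(net):
        raise ValueError("ASPL requires a connected graph")
    weight = _inv_weight if weighted else None
    return float(nx.average_shortest_path_length(net, weight=weight))


def partition_modularity(net: nx.Graph, communities) -> float:
    """Newman–Girvan Q of a given partition on the unweighted graph."""
    return float(nx.algorithms.community.modularity(net, communities, weight=None))


def modularity_q(
    net: nx.Graph, seed: int, restarts: int = 100
) -> tuple[float, list[frozenset]]:
    """Best-of-``restarts`` Louvain modularity on the unweighted graph.

    Each restart permutes the vertex order and reseeds the community
    detection, then the partition with the largest Newman–Girvan Q is kept.
    Returns ``(q, communities)``.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    nodes = sorted(net.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    edges = [(index[u], index[v]) for u, v in net.edges()]
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_membership: list[int] = [0] * n
    for _ in range(restarts):
        sub = int(rng.integers(2**31))
        perm = np.random.default_rng(sub).permutation(n)
        g = ig.Graph(n=n, edges=[(int(perm[a]), int(perm[b])) for a, b in edges])
        ig.set_random_number_generator(random.Random(sub))
        membership = g.community_multilevel().membership
        q = g.modularity(membership)
        if q > best_q:
            best_q = q
            best_membership = [membership[perm[i]] for i in range(n)]
    communities: dict[int, set] = {}
    for u in nodes:
        communities.setdefault(best_membership[index[u]], set()).add(u)
    parts = [frozenset(c) for c in communities.values()]
    return float(best_q), parts


def compute_metrics(
    net: nx.Graph, seed: int, restarts: int = 100, weighted: bool = False
) -> NetworkMetrics:
    """CC, ASPL and Q of one connected network."""
    q, parts = modularity_q(net, seed=seed, restarts=restarts)
    return NetworkMetrics(
        cc=clustering_coefficient(net, weighted=weighted),
        aspl=average_shortest_path_length(net, weighted=weighted),
        q=q,
        n_communities=len(parts),
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
    )
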