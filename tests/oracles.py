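"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — pure-Python loops, exhaustive
enumeration — and shares no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def tmfg_naive(labels, weights) -> set[frozenset]:
    """Greedy TMFG by literal exhaustive (node, face) scanning.

    Returns the edge set as frozensets of label pairs.  Ties break toward
    the smallest node label, then the earliest-created face.
    """
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    lab = [labels[i] for i in order]
    n = len(lab)
    w = [[float(weights[a][b]) for b in order] for a in order]

    totals = [(-sum(w[i]), i) for i in range(n)]
    seed = sorted(i for _, i in sorted(totals)[:4])
    edges = {frozenset((a, b)) for a, b in combinations(seed, 2)}
    faces = [tuple(f) for f in combinations(seed, 3)]
    remaining = [i for i in range(n) if i not in seed]

    while remaining:
        best = None  # (gain, node-rank, face-rank)
        for ri, v in enumerate(remaining):
            for fi, (a, b, c) in enumerate(faces):
                gain = w[v][a] + w[v][b] + w[v][c]
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, ri, fi)
        _, ri, fi = best
        v = remaining.pop(ri)
        a, b, c = faces.pop(fi)
        edges |= {frozenset((v, a)), frozenset((v, b)), frozenset((v, c))}
        faces += [(a, b, v), (a, c, v), (b, c, v)]
    return {frozenset(lab[i] for i in e) for e in edges}


def aspl_floyd_warshall(g: nx.Graph) -> float:
    """Unweighted ASPL via an all-pairs algorithm (not BFS)."""
    nodes = sorted(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    d = floyd_warshall(a, directed=False, unweighted=True)
    n = len(nodes)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_by_hand(g: nx.Graph, partition) -> float:
    """Newman–Girvan Q computed from its definition, no library call."""
    m = g.number_of_edges()
    q = 0.0
    for block in partition:
        block = set(block)
        e_c = sum(1 for u, v in g.edges() if u in block and v in block)
        d_c = sum(g.degree(u) for u in block)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def exhaustive_max_modularity(g: nx.Graph) -> float:
    """Maximum Q over all partitions (feasible up to ~8 nodes)."""
    return max(modularity_by_hand(g, p) for p in set_partitions(sorted(g.nodes())))
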