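"""Semantic network estimation from binary response matrices.

The estimation chain is: drop rare exemplars (produced by fewer than
``min_count`` participants in a group), equate the two groups onto their
shared exemplar set, compute the cosine association matrix, and filter it
with the triangulated maximally filtered graph (TMFG).  The TMFG keeps
exactly ``3n - 6`` of the strongest associations in a planar, connected
graph, so both groups' networks have identical node and edge counts and any
structural difference reflects how associations are arranged, not how many
survive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .fluency_io import ResponseMatrix

__all__ = [
    "AssociationMatrix",
    "EstimationError",
    "filter_min_occurrence",
    "equate_nodes",
    "cosine_association",
    "tmfg_filter",
    "write_graphml",
    "read_graphml",
    "write_edgelist_csv",
    "read_edgelist_csv",
]


class EstimationError(ValueError):
    """Raised when a response matrix cannot support network estimation."""


def filter_min_occurrence(mat: ResponseMatrix, min_count: int = 2) -> ResponseMatrix:
    """Keep exemplars produced by at least ``min_count`` participants.

    With the default of 2 this drops idiosyncratic single-participant
    responses, which would otherwise contribute only spurious associations.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keep = mat.data.columns[mat.column_sums() >= min_count]
    if len(keep) == 0:
        raise EstimationError(
            f"no exemplar reaches min_count={min_count}: insufficient shared vocabulary"
        )
    return ResponseMatrix(data=mat.data[keep].copy(), group=mat.group)


def equate_nodes(
    mat_a: ResponseMatrix, mat_b: ResponseMatrix
) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Restrict both matrices to their shared exemplars, same column order.

    Comparing networks over different node sets confounds structure with
    vocabulary; equating removes that confound.
    """
    shared = sorted(set(mat_a.exemplars) & set(mat_b.exemplars))
    if not shared:
        raise EstimationError("groups share no exemplars after filtering")
    return (
        ResponseMatrix(data=mat_a.data[shared].copy(), group=mat_a.group),
        ResponseMatrix(data=mat_b.data[shared].copy(), group=mat_b.group),
    )


@dataclass
class AssociationMatrix:
    """Symmetric exemplar x exemplar cosine co-occurrence matrix.

    ``values[i, j] = c_ij / sqrt(f_i * f_j)`` where ``c_ij`` is the number of
    participants producing both exemplars and ``f_i`` the production
    frequency of exemplar ``i``; entries lie in [0, 1], diagonal stored as 0.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("association matrix must be square and match labels")
        if not np.allclose(v, v.T):
            raise ValueError("association matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)


def cosine_association(mat: ResponseMatrix) -> AssociationMatrix:
    """Cosine similarity between exemplar occurrence vectors.

    0 means two exemplars never co-occur in a participant's list, 1 means
    they always co-occur.
    """
    if mat.n_exemplars < 2:
        raise EstimationError("need at least two exemplars for associations")
    m = mat.data.to_numpy().astype(float)
    freq = m.sum(axis=0)
    if np.any(freq == 0):
        zero = [c for c, f in zip(mat.exemplars, freq) if f == 0]
        raise EstimationError(f"zero-frequency exemplars {zero}; filter first")
    co = m.T @ m
    values = co / np.sqrt(np.outer(freq, freq))
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(labels=tuple(mat.exemplars), values=values)


def tmfg_filter(assoc: AssociationMatrix, group: str | None = None) -> nx.Graph:
    """Triangulated maximally filtered graph of an association matrix.

    Greedy construction: seed with the four nodes of greatest total
    association connected as K4, keep the list of triangular faces, and
    repeatedly insert the (node, face) pair with the largest three-edge gain
    ``w(v,a) + w(v,b) + w(v,c)``, splitting the host face into three.  The
    result is planar and connected with exactly ``3n - 6`` edges.

    Ties are broken toward the lexicographically smallest node label, then
    the earliest-created face, making the output deterministic.
    """
    n = assoc.n
    if n < 4:
        raise EstimationError(f"TMFG needs at least 4 nodes, got {n}")
    if np.any(assoc.values < 0):
        raise EstimationError("TMFG requires nonnegative associations")
    if not np.any(assoc.values > 0):
        raise EstimationError("all-zero association matrix")

    # Work in lexicographic label order so index order == tie-break order.
    order = sorted(range(n), key=lambda i: assoc.labels[i])
    labels = [assoc.labels[i] for i in order]
    w = assoc.values[np.ix_(order, order)]

    totals = w.sum(axis=1)
    # Highest total association first; ties toward the smaller label.
    seed = sorted(np.lexsort((np.arange(n), -totals))[:4].tolist())
    edges: list[tuple[int, int]] = [
        (a, b) for k, a in enumerate(seed) for b in seed[k + 1 :]
    ]
    faces: list[tuple[int, int, int]] = [
        (seed[0], seed[1], seed[2]),
        (seed[0], seed[1], seed[3]),
        (seed[0], seed[2], seed[3]),
        (seed[1], seed[2], seed[3]),
    ]
    remaining = [i for i in range(n) if i not in seed]

    while remaining:
        rem = np.array(remaining)
        face_arr = np.array(faces)
        # gains[i, j] = total association of remaining node i to face j
        gains = w[rem][:, face_arr].sum(axis=2)
        # argmax scans row-major: smallest node label first, then earliest face
        i, j = divmod(int(np.argmax(gains)), len(faces))
        v = remaining.pop(i)
        a, b, c = faces.pop(j)
        edges.extend([(v, a), (v, b), (v, c)])
        faces.extend([(a, b, v), (a, c, v), (b, c, v)])

    net = nx.Graph()
    net.add_nodes_from(labels)
    for u, v in edges:
        net.add_edge(labels[u], labels[v], weight=float(w[u, v]))
    if net.number_of_edges() != 3 * n - 6:
        raise RuntimeError("TMFG invariant violated: edge count != 3n - 6")
    if group is not None:
        net.graph["group"] = group
    return net


# ---------------------------------------------------------------------------
# Network I/O

def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_edgelist_csv(net: nx.Graph, path: str | Path) -> None:
    """Write a `source,target,weight` edge list (lexicographic edge order)."""
    rows = sorted(
        (min(u, v), max(u, v), d.get("weight", 1.0)) for u, v, d in net.edges(data=True)
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for u, v, wt in rows:
            writer.writerow([u, v, repr(float(wt))])


def read_edgelist_csv(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            net.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return net
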