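"""Erdős–Rényi null models for the empirical network measures.

An observed CC, ASPL or Q is only meaningful against what size-matched
random graphs produce.  The ensemble draws G(n, p) graphs with
``p = m / C(n, 2)`` (or exactly-m G(n, m) graphs), computes the three
measures on each draw, and compares the empirical value against the
resulting sampling distribution with an add-one two-sided percentile
p-value, so p is never exactly zero and the attainable floor is
``2 / (iters + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network_metrics import (
    NetworkMetrics,
    clustering_coefficient,
    modularity_q,
)

__all__ = [
    "MetricDistribution",
    "ERCEnsemble",
    "simulate_er_ensemble",
    "percentile_p_value",
    "null_comparison_report",
]

MEASURES = ("cc", "aspl", "q")


@dataclass
class MetricDistribution:
    """A vector of simulated values of one network measure."""

    measure: str
    values: np.ndarray
    seed: int
    provenance: str  # "random_ensemble" or "bootstrap"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric distribution contains non-finite values")

    @property
    def iters(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(self.values.mean())

    def sd(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass
class ERCEnsemble:
    """Distributions of CC/ASPL/Q over an Erdős–Rényi ensemble."""

    n: int
    m: int
    model: str
    seed: int
    cc: MetricDistribution
    aspl: MetricDistribution
    q: MetricDistribution
    n_edges: np.ndarray = field(repr=False)

    def distribution(self, measure: str) -> MetricDistribution:
        return {"cc": self.cc, "aspl": self.aspl, "q": self.q}[measure]


def _largest_component_aspl(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    if nx.is_connected(g):
        return float(nx.average_shortest_path_length(g))
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        return 0.0
    return float(nx.average_shortest_path_length(g.subgraph(comp)))


def simulate_er_ensemble(
    n: int,
    m: int,
    iters: int = 1000,
    seed: int = 0,
    model: str = "gnp",
    louvain_restarts: int = 25,
) -> ERCEnsemble:
    """Sampling distributions of CC/ASPL/Q under size-matched random graphs.

    ``model="gnp"`` fixes the edge probability at ``p = m / C(n, 2)``;
    ``model="gnm"`` fixes the edge count at exactly ``m``.  ASPL of a
    disconnected draw is computed on its largest connected component.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    max_edges = n * (n - 1) // 2
    if not 0 < m <= max_edges:
        raise ValueError(f"m must be in (0, {max_edges}]")
    if model not in {"gnp", "gnm"}:
        raise ValueError("model must be 'gnp' or 'gnm'")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    p = m / max_edges
    rng = np.random.default_rng(seed)
    cc = np.empty(iters)
    aspl = np.empty(iters)
    q = np.empty(iters)
    n_edges = np.empty(iters, dtype=int)
    for i in range(iters):
        gseed = int(rng.integers(2**31))
        if model == "gnp":
            g = nx.fast_gnp_random_graph(n, p, seed=gseed)
        else:
            g = nx.gnm_random_graph(n, m, seed=gseed)
        n_edges[i] = g.number_of_edges()
        cc[i] = clustering_coefficient(g)
        aspl[i] = _largest_component_aspl(g)
        if g.number_of_edges() == 0:
            q[i] = 0.0
        else:
            q[i], _ = modularity_q(g, seed=int(rng.integers(2**31)), restarts=louvain_restarts)
    return ERCEnsemble(
        n=n,
        m=m,
        model=model,
        seed=seed,
        cc=MetricDistribution("cc", cc, seed, "random_ensemble"),
        aspl=MetricDistribution("aspl", aspl, seed, "random_ensemble"),
        q=MetricDistribution("q", q, seed, "random_ensemble"),
        n_edges=n_edges,
    )


def percentile_p_value(empirical: float, dist: MetricDistribution) -> float:
    """Two-sided add-one percentile p of an empirical value in a distribution.

    ``p = 2 * (1 + min(#below-or-equal, #above-or-equal)) / (iters + 1)``,
    capped at 1.  The smallest attainable p with ``iters`` simulations is
    ``2 / (iters + 1)``.
    """
    if dist.iters == 0:
        raise ValueError("empty distribution")
    le = int(np.sum(dist.values <= empirical))
    ge = int(np.sum(dist.values >= empirical))
    p = 2.0 * (1 + min(le, ge)) / (dist.iters + 1)
    return min(p, 1.0)


def null_comparison_report(
    metrics: NetworkMetrics, ensemble: ERCEnsemble, group: str | None = None
) -> dict:
    """Per-measure JSON-ready comparison of a network against its null."""
    empirical = {"cc": metrics.cc, "aspl": metrics.aspl, "q": metrics.q}
    report: dict = {"group": group, "model": ensemble.model, "n": ensemble.n, "m": ensemble.m}
    floor = 2.0 / (ensemble.cc.iters + 1)
    for measure in MEASURES:
        dist = ensemble.distribution(measure)
        report[measure] = {
            "empirical": empirical[measure],
            "null_mean": dist.mean(),
            "null_sd": dist.sd(),
            "p_two_sided": percentile_p_value(empirical[measure], dist),
            "p_floor": floor,
            "iters": dist.iters,
            "seed": dist.seed,
            "model": ensemble.model,
        }
    return report
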