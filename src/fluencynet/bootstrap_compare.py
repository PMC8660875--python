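"""Case-wise bootstrap of group networks and distribution comparison.

Each bootstrap iteration resamples participants with replacement (to the
original group size), re-runs the full estimation chain — minimum-occurrence
filter, cross-group node equating, cosine association, TMFG — and records
CC/ASPL/Q for both groups.  The resulting measure distributions are compared
with independent-group Student t tests and pooled-SD Cohen's d.

Node equating is re-applied within every iteration by default (the fully
case-wise reading); ``equate_each_iteration=False`` instead fixes the node
set to the full-sample shared exemplars.  Iterations whose resample cannot
support estimation (too few shared exemplars) are redrawn, and the redraw
count is reported, so the distributions always have length ``iters``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fluency_io import ResponseMatrix
from .network_estimation import (
    EstimationError,
    cosine_association,
    equate_nodes,
    filter_min_occurrence,
    tmfg_filter,
)
from .network_metrics import (
    average_shortest_path_length,
    clustering_coefficient,
    modularity_q,
)
from .null_models import MEASURES, MetricDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "ComparisonResult",
    "casewise_bootstrap",
    "compare_distributions",
    "compare_groups",
    "effect_size_label",
]


@dataclass
class BootstrapResult:
    """Per-group bootstrap distributions of cc/aspl/q plus bookkeeping.

    Distributions are stored positionally (side 0 = first matrix passed,
    side 1 = second) so the two arms may legitimately carry the same label,
    e.g. when bootstrapping one group against itself as a calibration check.
    """

    groups: tuple[str, str]
    distributions: tuple[dict, dict]  # per side: {measure: MetricDistribution}
    iters: int
    seed: int
    n_redraws: int

    def distribution(self, measure: str, side: int) -> MetricDistribution:
        return self.distributions[side][measure]


def _group_stream(seed: int, iteration: int, attempt: int, group: str) -> np.random.Generator:
    # Group identity enters via a stable label hash, so two matrices with the
    # same label (and content) draw the same resamples.
    tag = zlib.crc32(group.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([seed, iteration, attempt, tag])


def _resample(mat: ResponseMatrix, rng: np.random.Generator) -> ResponseMatrix:
    n = mat.n_participants
    idx = rng.integers(0, n, size=n)
    data = mat.data.iloc[idx].copy()
    data.index = [f"b{k}" for k in range(n)]
    return ResponseMatrix(data=data, group=mat.group)


def _restrict_to_fixed(
    a: ResponseMatrix, b: ResponseMatrix, fixed: list[str]
) -> tuple[ResponseMatrix, ResponseMatrix]:
    cols_a = a.data[fixed]
    cols_b = b.data[fixed]
    keep = [
        c
        for c in fixed
        if cols_a[c].to_numpy().sum() > 0 and cols_b[c].to_numpy().sum() > 0
    ]
    if not keep:
        raise EstimationError("fixed node set absent from this resample")
    return (
        ResponseMatrix(data=cols_a[keep].copy(), group=a.group),
        ResponseMatrix(data=cols_b[keep].copy(), group=b.group),
    )


def casewise_bootstrap(
    mat_a: ResponseMatrix,
    mat_b: ResponseMatrix,
    iters: int = 1000,
    seed: int = 0,
    min_count: int = 2,
    equate_each_iteration: bool = True,
    louvain_restarts: int = 25,
    weighted: bool = False,
    max_redraws_per_iter: int = 200,
) -> BootstrapResult:
    """Bootstrap distributions of cc/aspl/q for two groups.

    ``mat_a`` and ``mat_b`` are the raw (pre-filter) group response
    matrices.  Returns three :class:`MetricDistribution` objects per group.
    """
    if iters < 2:
        raise ValueError("iters must be >= 2")
    values = [
        {meas: np.empty(iters) for meas in MEASURES},
        {meas: np.empty(iters) for meas in MEASURES},
    ]

    fixed_nodes: list[str] | None = None
    if not equate_each_iteration:
        ea, eb = equate_nodes(
            filter_min_occurrence(mat_a, min_count),
            filter_min_occurrence(mat_b, min_count),
        )
        fixed_nodes = ea.exemplars

    n_redraws = 0
    for i in range(iters):
        for attempt in range(max_redraws_per_iter + 1):
            rng_a = _group_stream(seed, i, attempt, mat_a.group)
            rng_b = _group_stream(seed, i, attempt, mat_b.group)
            try:
                ra = _resample(mat_a, rng_a)
                rb = _resample(mat_b, rng_b)
                if equate_each_iteration:
                    ea, eb = equate_nodes(
                        filter_min_occurrence(ra, min_count),
                        filter_min_occurrence(rb, min_count),
                    )
                else:
                    assert fixed_nodes is not None
                    ea, eb = _restrict_to_fixed(ra, rb, fixed_nodes)
                if ea.n_exemplars < 4:
                    raise EstimationError("fewer than 4 shared exemplars")
                for side, (mat, rng) in enumerate(((ea, rng_a), (eb, rng_b))):
                    net = tmfg_filter(cosine_association(mat), group=mat.group)
                    values[side]["cc"][i] = clustering_coefficient(net, weighted)
                    values[side]["aspl"][i] = average_shortest_path_length(
                        net, weighted
                    )
                    values[side]["q"][i] = modularity_q(
                        net, seed=int(rng.integers(2**31)), restarts=louvain_restarts
                    )[0]
                break
            except EstimationError as exc:
                n_redraws += 1
                logger.debug("iteration %d attempt %d redrawn: %s", i, attempt, exc)
        else:
            raise EstimationError(
                f"iteration {i} failed after {max_redraws_per_iter} redraws"
            )
    if n_redraws:
        logger.info("case-wise bootstrap redrew %d failed resamples", n_redraws)

    distributions = tuple(
        {
            meas: MetricDistribution(meas, vals, seed, "bootstrap")
            for meas, vals in by_measure.items()
        }
        for by_measure in values
    )
    return BootstrapResult(
        groups=(mat_a.group, mat_b.group),
        distributions=distributions,
        iters=iters,
        seed=seed,
        n_redraws=n_redraws,
    )


def effect_size_label(d: float) -> str:
    """Benchmark labels for |d|: 0.20 small, 0.50 moderate, 0.80 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    if a >= 0.2:
        return "small"
    return "negligible"


@dataclass
class ComparisonResult:
    """Student t comparison of two bootstrap measure distributions."""

    measure: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p: float
    d: float

    @property
    def effect_label(self) -> str:
        return effect_size_label(self.d)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "d": self.d,
            "effect": self.effect_label,
        }


def compare_distributions(
    dist_a: MetricDistribution,
    dist_b: MetricDistribution,
    group_a: str = "A",
    group_b: str = "B",
) -> ComparisonResult:
    """Pooled-variance Student t and Cohen's d between two distributions.

    The pooled convention gives ``df = n_a + n_b - 2`` (1998 for two runs of
    1000 iterations); ``d`` carries the sign of ``mean_a - mean_b``.
    """
    if dist_a.measure != dist_b.measure:
        raise ValueError("distributions measure different quantities")
    a, b = dist_a.values, dist_b.values
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least two values per distribution")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance: distributions are constant")
    diff = a.mean() - b.mean()
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / np.sqrt(pooled)
    return ComparisonResult(
        measure=dist_a.measure,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        df=df,
        p=float(p),
        d=float(d),
    )


def compare_groups(result: BootstrapResult) -> list[ComparisonResult]:
    """One :class:`ComparisonResult` per measure (cc, aspl, q)."""
    ga, gb = result.groups
    return [
        compare_distributions(
            result.distribution(meas, 0), result.distribution(meas, 1), ga, gb
        )
        for meas in MEASURES
    ]
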