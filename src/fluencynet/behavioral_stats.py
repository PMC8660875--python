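"""Group-comparison statistics for demographic, fluency and creativity scores.

Raw per-participant data for such studies are often unavailable, so the t
test accepts either raw vectors or published mean/SD/n summaries — the
pooled-variance statistics are identical either way.  When raw vectors are
supplied, a Levene test (median-centred) decides between Student and Welch
variants unless the caller forces one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "independent_t",
    "chi_square_2x2",
    "pearson_r",
    "summarize",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and n of one group's scores."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    d: float
    welch: bool
    levene_p: float | None


def summarize(x: Sequence[float]) -> GroupSummary:
    arr = np.asarray(x, dtype=float)
    return GroupSummary(float(arr.mean()), float(arr.std(ddof=1)), len(arr))


def _as_summary(x) -> tuple[GroupSummary, np.ndarray | None]:
    if isinstance(x, GroupSummary):
        return x, None
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("raw vectors must be 1-D with length >= 2")
    return summarize(arr), arr


def independent_t(a, b, welch: bool | None = None) -> TTestResult:
    """Independent-groups t test from raw vectors or mean/SD/n summaries.

    Defaults to the pooled-variance Student test (df = n_a + n_b - 2).  With
    raw vectors and ``welch=None``, a median-centred Levene test selects
    Welch's test at p < 0.05.  Cohen's d always uses the pooled SD with
    (n - 1) weights, so d from raw vectors equals d from exact summaries.
    """
    sa, raw_a = _as_summary(a)
    sb, raw_b = _as_summary(b)
    levene_p: float | None = None
    if welch is None:
        if raw_a is not None and raw_b is not None:
            levene_p = float(stats.levene(raw_a, raw_b, center="median").pvalue)
            welch = levene_p < 0.05
        else:
            welch = False

    va, vb = sa.sd**2, sb.sd**2
    na, nb = sa.n, sb.n
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero variance in both groups")
    diff = sa.mean - sb.mean
    d = diff / np.sqrt(pooled)

    if welch:
        se2 = va / na + vb / nb
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(d), bool(welch), levene_p)


def chi_square_2x2(table) -> tuple[float, int, float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table.

    Returns ``(chi2, df=1, p, phi)`` with ``phi = sqrt(chi2 / N)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in the table")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    phi = float(np.sqrt(chi2 / t.sum()))
    return float(chi2), int(df), float(p), phi


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(xa) < 3:
        raise ValueError("need at least three pairs")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("constant input has undefined correlation")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)
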