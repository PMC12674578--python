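"""Nonparametric comparison of per-block vocalization counts.

Per-block count data are small, discrete and heavily tied, so the battery
is rank-based throughout: a Mann-Whitney U test for two conditions
(pooled structured activity vs the overnight baseline), Kruskal-Wallis
across the four contexts, Dunn's post hoc pairwise z tests with Bonferroni
correction, and Gaussian kernel density estimates of the count
distributions per condition.

The Mann-Whitney test is exact (full enumeration of all C(n+m, n)
labelings, midranks for ties) when both groups have at most
``EXACT_MAX_N`` observations, and otherwise uses the tie-corrected normal
approximation.  Dunn's z for groups i, j uses pooled midranks:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

with tie term T = sum(t^3 - t) / (12 (N - 1)) over tie groups; the
Bonferroni multiplier is the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "EXACT_MAX_N",
    "StatTestResult",
    "PairwiseTable",
    "KdeCurve",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "kde_counts",
]

#: Largest per-group size for which the Mann-Whitney p is computed by
#: exact enumeration; beyond this the normal approximation takes over.
EXACT_MAX_N = 8


@dataclass
class StatTestResult:
    method: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PairwiseTable:
    """Dunn post hoc results: one z and raw/adjusted p per group pair."""

    pairs: list[tuple[str, str]]
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray


@dataclass
class KdeCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: pairwise wins over b, ties counting 1/2."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all labelings of the pooled sample.

    P(|U - nm/2| >= |u_obs - nm/2|) over all C(n+m, n) assignments of the
    pooled values to group a; ties handled by the values themselves.
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    center = n * m / 2.0
    dev_obs = abs(_u_statistic(a, b) - center)
    hits = 0
    idx_all = frozenset(range(n + m))
    for idx_a in combinations(range(n + m), n):
        idx_b = sorted(idx_all - set(idx_a))
        u = _u_statistic(pooled[list(idx_a)], pooled[idx_b])
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    return hits / comb(n + m, n)


def mann_whitney_u(
    a, b, alternative: str = "two-sided", *, method: str = "auto"
) -> StatTestResult:
    """Mann-Whitney U test between two count samples.

    ``method="auto"`` selects exact enumeration when both groups have at
    most :data:`EXACT_MAX_N` observations (exact only supports the
    two-sided alternative), else the tie-corrected normal approximation
    with continuity correction.  The reported statistic is U of the first
    sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_a = _u_statistic(a, b)
    if method == "auto":
        method = (
            "exact"
            if (a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and alternative == "two-sided")
            else "asymptotic"
        )
    if method == "exact":
        if alternative != "two-sided":
            raise ValueError("exact enumeration implements the two-sided alternative only")
        p = _exact_mw_p(a, b)
        used = "mann-whitney-exact"
    elif method == "asymptotic":
        _, p = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        p = float(p)
        used = "mann-whitney-asymptotic"
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatTestResult(
        method=used,
        statistic=u_a,
        p_value=min(1.0, p),
        groups=("a", "b"),
        n_per_group=(a.size, b.size),
    )


def kruskal_wallis(groups: dict[str, np.ndarray] | list) -> StatTestResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected).

    When every pooled value is identical H = 0 and p = 1 by convention.
    """
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        samples = [np.asarray(groups[k], float) for k in labels]
    else:
        samples = [np.asarray(g, float) for g in groups]
        labels = tuple(f"g{i}" for i in range(len(samples)))
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return StatTestResult(
        method="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        groups=labels,
        n_per_group=tuple(s.size for s in samples),
    )


def dunn_posthoc(
    groups: dict[str, np.ndarray], correction: str = "bonferroni"
) -> PairwiseTable:
    """Dunn's post hoc pairwise z tests on pooled midranks.

    Requires >= 3 groups (with two conditions use
    :func:`mann_whitney_u`).  ``correction`` is ``"bonferroni"``
    (p_adj = min(1, n_pairs * p_raw)) or ``"none"``.
    """
    labels = list(groups.keys())
    samples = [np.asarray(groups[k], float) for k in labels]
    if len(samples) < 3:
        raise ValueError("Dunn's test needs >= 3 groups; use mann_whitney_u for 2")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for s in samples:
        mean_ranks.append(ranks[offset : offset + s.size].mean())
        sizes.append(s.size)
        offset += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, zs, praw = [], [], []
    for i, j in combinations(range(len(samples)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((labels[i], labels[j]))
        zs.append(z)
        praw.append(2.0 * stats.norm.sf(abs(z)))
    praw = np.asarray(praw)
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, len(pairs) * praw)
    elif correction == "none":
        p_adj = praw.copy()
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return PairwiseTable(pairs=pairs, z=np.asarray(zs), p_raw=praw, p_adjusted=p_adj)


def kde_counts(
    counts,
    bandwidth: float = 0.4,
    grid: np.ndarray | None = None,
    *,
    bandwidth_mode: str = "absolute",
) -> KdeCurve:
    """Gaussian kernel density estimate of per-block counts.

    density(x) = (1 / (n h)) * sum_i phi((x - c_i) / h), phi the standard
    normal pdf.  ``bandwidth_mode="absolute"`` (default) uses ``bandwidth``
    in count units; ``"factor"`` scales it by the sample standard
    deviation, matching KDE softwares that treat the bandwidth argument as
    a factor.  The default grid spans the data range extended by 5
    bandwidths on each side, in steps <= h/10, so the curve integrates to
    1 to within 1e-3 by the trapezoid rule.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if bandwidth_mode == "factor":
        sd = counts.std(ddof=1) if counts.size > 1 else 1.0
        h = bandwidth * (sd if sd > 0 else 1.0)
    elif bandwidth_mode == "absolute":
        h = bandwidth
    else:
        raise ValueError(f"unknown bandwidth_mode {bandwidth_mode!r}")
    if grid is None:
        lo = counts.min() - 5.0 * h
        hi = counts.max() + 5.0 * h
        n_pts = max(201, int(np.ceil((hi - lo) / (h / 10.0))) + 1)
        grid = np.linspace(lo, hi, n_pts)
    else:
        grid = np.asarray(grid, dtype=float)
    density = stats.norm.pdf((grid[:, None] - counts[None, :]) / h).sum(axis=1) / (
        counts.size * h
    )
    return KdeCurve(grid=grid, density=density, bandwidth=h)
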