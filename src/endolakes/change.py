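"""Two-period change statistics: Wilcoxon rank-sum tests, linear trends,
percent-change rollups, and lake change vectors.

The comparison periods are P1 = 1984-1999 (n=16) and P2 = 2000-2018 with the
2012 satellite gap removed (n=18). Percent differences are rounded
half-away-from-zero so printed integer summaries are reproduced
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PeriodDefinition",
    "PeriodSummary",
    "ChangeVector",
    "TrendResult",
    "RegionalRollup",
    "percent_change",
    "wilcoxon_rank_sum",
    "linear_trend",
    "period_summary",
    "change_vector",
    "regional_rollup",
]

#: Largest group size for which the exact Wilcoxon null is enumerated.
EXACT_ENUMERATION_LIMIT = 10


@dataclass(frozen=True)
class PeriodDefinition:
    """Two disjoint, ordered year bins for before/after comparison."""

    p1: tuple[int, ...]
    p2: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.p1 or not self.p2:
            raise ValueError("both periods must be nonempty")
        if set(self.p1) & set(self.p2):
            raise ValueError("periods must be disjoint")
        if max(self.p1) >= min(self.p2):
            raise ValueError("P1 must entirely precede P2")

    @classmethod
    def default(cls) -> "PeriodDefinition":
        """1984-1999 vs 2000-2018 excluding the 2012 satellite gap."""
        return cls(
            p1=tuple(range(1984, 2000)),
            p2=tuple(y for y in range(2000, 2019) if y != 2012),
        )


def percent_change(m1: float, m2: float) -> int:
    """Integer percent difference 100*(m2-m1)/m1, rounded half away from zero."""
    if m1 == 0:
        raise ValueError("percent change undefined for zero baseline")
    pct = 100.0 * (m2 - m1) / m1
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mann-Whitney U for sample x (midrank ties) and the pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    u1 = r1 - len(x) * (len(x) + 1) / 2.0
    return u1, ranks


def _exact_p(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Two-sided exact p by enumerating all C(N, n1) labelings (no ties)."""
    n = len(ranks)
    base = np.asarray(ranks, dtype=float)
    offset = n1 * (n1 + 1) / 2.0
    us = np.fromiter(
        (sum(c) - offset for c in combinations(base, n1)),
        dtype=float,
    )
    u2 = n1 * (n - n1) - u1
    u_obs = min(u1, u2)
    total = len(us)
    p = 2.0 * np.count_nonzero(us <= u_obs + 1e-9) / total
    return min(1.0, p)


def _approx_p(x: np.ndarray, y: np.ndarray, u1: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0  # all observations tied: identical distributions
    diff = u1 - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sample Wilcoxon / Mann-Whitney test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of the first
    sample and p is two-sided. ``method='auto'`` enumerates the exact null
    when max(n1, n2) <= 10 and there are no ties, else uses the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    u1, ranks = _rank_sum_u(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    small = max(x.size, y.size) <= EXACT_ENUMERATION_LIMIT
    if method == "exact" or (method == "auto" and small and not has_ties):
        if has_ties:
            raise ValueError("exact enumeration requires tie-free samples")
        return u1, _exact_p(ranks, x.size, u1)
    return u1, _approx_p(x, y, u1)


@dataclass(frozen=True)
class TrendResult:
    """OLS slope against year with a two-sided t-test on the slope.

    ``degenerate`` flags a constant response, for which the t statistic is
    undefined (slope 0, p NaN by documented convention).
    """

    slope: float
    se: float
    p: float
    intercept: float
    degenerate: bool = False


def linear_trend(years: Sequence[float], values: Sequence[float]) -> TrendResult:
    """Ordinary least squares of values on year; NaN observations are skipped."""
    years = np.asarray(list(years), dtype=float)
    values = np.asarray(list(values), dtype=float)
    keep = np.isfinite(values) & np.isfinite(years)
    years, values = years[keep], values[keep]
    if years.size < 3:
        raise ValueError("linear trend needs at least 3 observations")
    if np.ptp(years) == 0:
        raise ValueError("all years identical; trend undefined")
    if np.ptp(values) == 0:
        return TrendResult(slope=0.0, se=0.0, p=float("nan"),
                           intercept=float(values[0]), degenerate=True)
    res = stats.linregress(years, values)
    return TrendResult(
        slope=float(res.slope),
        se=float(res.stderr),
        p=float(res.pvalue),
        intercept=float(res.intercept),
    )


@dataclass(frozen=True)
class PeriodSummary:
    """Mean/SD per period plus change, Wilcoxon, and linear-trend statistics."""

    p1_mean: float
    p1_sd: float
    p2_mean: float
    p2_sd: float
    change: float
    percent: int
    u: float
    wilcoxon_p: float
    slope: float
    slope_se: float
    trend_p: float
    n1: int
    n2: int


def _split_periods(
    years: Sequence[float], values: Sequence[float], periods: PeriodDefinition
) -> tuple[np.ndarray, np.ndarray]:
    years = np.asarray(list(years))
    values = np.asarray(list(values), dtype=float)
    keep = np.isfinite(values)
    years, values = years[keep], values[keep]
    v1 = values[np.isin(years, periods.p1)]
    v2 = values[np.isin(years, periods.p2)]
    return v1, v2


def period_summary(
    years: Sequence[float],
    values: Sequence[float],
    periods: PeriodDefinition | None = None,
) -> PeriodSummary:
    """Full two-period summary of an annual series; missing years are skipped."""
    if periods is None:
        periods = PeriodDefinition.default()
    v1, v2 = _split_periods(years, values, periods)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError(
            f"need >=2 observations per period, got {len(v1)} and {len(v2)}"
        )
    m1, m2 = float(np.mean(v1)), float(np.mean(v2))
    u, p = wilcoxon_rank_sum(v1, v2)
    yrs = np.asarray(list(years))
    vals = np.asarray(list(values), dtype=float)
    in_periods = np.isin(yrs, periods.p1 + periods.p2)
    trend = linear_trend(yrs[in_periods], vals[in_periods])
    return PeriodSummary(
        p1_mean=m1,
        p1_sd=float(np.std(v1, ddof=1)),
        p2_mean=m2,
        p2_sd=float(np.std(v2, ddof=1)),
        change=m2 - m1,
        percent=percent_change(m1, m2),
        u=u,
        wilcoxon_p=p,
        slope=trend.slope,
        slope_se=trend.se,
        trend_p=trend.p,
        n1=len(v1),
        n2=len(v2),
    )


@dataclass(frozen=True)
class ChangeVector:
    """Lake state transition between periods in (proportion, variance) space.

    Annual areas are normalized by the maximum area over the full record, so
    proportions lie in [0, 1] and the vector is invariant to rescaling all
    areas by a positive constant.
    """

    p1_mean: float
    p2_mean: float
    p1_var: float
    p2_var: float

    @property
    def d_mean(self) -> float:
        return self.p2_mean - self.p1_mean

    @property
    def d_var(self) -> float:
        return self.p2_var - self.p1_var

    @property
    def magnitude(self) -> float:
        return math.hypot(self.d_mean, self.d_var)

    @property
    def direction(self) -> float:
        """Angle (radians) of the change vector in (d_mean, d_var) space."""
        return math.atan2(self.d_var, self.d_mean)


def change_vector(
    years: Sequence[float],
    areas: Sequence[float],
    periods: PeriodDefinition | None = None,
) -> ChangeVector:
    """Per-period mean and variance of the proportion-of-maximum series."""
    if periods is None:
        periods = PeriodDefinition.default()
    areas = np.asarray(list(areas), dtype=float)
    finite = areas[np.isfinite(areas)]
    if finite.size == 0 or np.nanmax(finite) <= 0:
        raise ValueError("record maximum area must be positive")
    props = areas / np.nanmax(finite)
    v1, v2 = _split_periods(years, props, periods)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("need >=2 observations per period")
    return ChangeVector(
        p1_mean=float(np.mean(v1)),
        p2_mean=float(np.mean(v2)),
        p1_var=float(np.var(v1, ddof=1)),
        p2_var=float(np.var(v2, ddof=1)),
    )


@dataclass(frozen=True)
class RegionalRollup:
    """Region-level totals: period means of the summed series plus counts of
    watersheds individually significant by Wilcoxon and by linear trend."""

    p1_mean: float
    p2_mean: float
    change: float
    percent: int
    n_watersheds: int
    n_wilcoxon_sig: int
    n_trend_sig: int


def regional_rollup(
    series_by_watershed: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    periods: PeriodDefinition | None = None,
    alpha: float = 0.05,
    units: Mapping[str, str] | None = None,
) -> RegionalRollup:
    """Pool watershed series by summing per year, then summarize the sum.

    ``series_by_watershed`` maps watershed id -> (years, values). If ``units``
    is given, mixing different unit strings raises.
    """
    if not series_by_watershed:
        raise ValueError("no watershed series supplied")
    if units is not None and len(set(units.values())) > 1:
        raise ValueError(f"mixed units in rollup: {sorted(set(units.values()))}")
    if periods is None:
        periods = PeriodDefinition.default()

    totals: dict[float, float] = {}
    counts: dict[float, int] = {}
    n_wilcox = 0
    n_trend = 0
    for _, (years, values) in series_by_watershed.items():
        summ = period_summary(years, values, periods)
        n_wilcox += summ.wilcoxon_p < alpha
        n_trend += summ.trend_p < alpha
        for year, val in zip(years, values):
            if np.isfinite(val):
                totals[year] = totals.get(year, 0.0) + float(val)
                counts[year] = counts.get(year, 0) + 1
    # Only years observed in every watershed enter the pooled sum, so a
    # missing year in one series cannot masquerade as a regional decline.
    n_sheds = len(series_by_watershed)
    pooled_years = sorted(y for y, c in counts.items() if c == n_sheds)
    pooled = [totals[y] for y in pooled_years]
    summ = period_summary(pooled_years, pooled, periods)
    return RegionalRollup(
        p1_mean=summ.p1_mean,
        p2_mean=summ.p2_mean,
        change=summ.change,
        percent=summ.percent,
        n_watersheds=n_sheds,
        n_wilcoxon_sig=int(n_wilcox),
        n_trend_sig=int(n_trend),
    )
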