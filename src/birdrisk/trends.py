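"""Long-term and seasonal structure of BSRI per airbase.

Two complementary summaries of an airbase's BSRI history:

* linear trends — ordinary least squares of monthly mean BSRI on time in
  fractional years, over the whole record or the last 120 months, reported
  as slope per year with adjusted R² and residual degrees of freedom;
* seasonal profiles — daily means over day-of-year smoothed with a periodic
  (cyclic) second-difference penalty, the discrete analogue of a cyclic
  smoothing spline.  The penalty weight is picked by generalized
  cross-validation unless fixed.

The smoother is linear in the daily means, reproduces constants exactly and
shrinks to the grand mean as the penalty grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bsri import BSRIResult

__all__ = [
    "TrendResult",
    "SeasonalProfile",
    "monthly_means",
    "linear_trend",
    "last_10_years",
    "seasonal_profile",
    "significance_stars",
    "trend_table",
]

_DAYS_IN_GRID = 366  # day-of-year grid; day 366 wraps to day 1


@dataclass(frozen=True)
class TrendResult:
    airbase: str
    period: tuple[str, str]  # first and last month, "YYYY-MM"
    slope_per_year: float
    adj_r_squared: float
    df: int  # residual degrees of freedom, n_months - 2
    p_value: float
    n_months: int


@dataclass(frozen=True)
class SeasonalProfile:
    airbase: str
    day_of_year: np.ndarray  # 1..366
    bsri: np.ndarray  # smoothed mean BSRI per day
    smoothing: float  # penalty weight actually used


def monthly_means(results: Sequence[BSRIResult], airbase: str) -> pd.Series:
    """Mean BSRI per calendar month for one airbase.

    Months without inspections are simply absent (not zero).  The index is a
    monthly ``PeriodIndex``.
    """
    rows = [(r.timestamp, r.bsri) for r in results if r.airbase == airbase]
    if not rows:
        raise ValueError(f"no BSRI results for airbase {airbase!r}")
    s = pd.Series(
        [b for _, b in rows],
        index=pd.DatetimeIndex([t for t, _ in rows]),
        name="bsri",
    )
    return s.groupby(s.index.to_period("M")).mean().sort_index()


def last_10_years(series: pd.Series) -> pd.Series:
    """Restrict a monthly series to the 120 calendar months ending at its
    final observed month."""
    end = series.index.max()
    start = end - 119
    return series[series.index >= start]


def linear_trend(series: pd.Series, airbase: str = "") -> TrendResult:
    """OLS of monthly mean BSRI on time in fractional years.

    Time is centred at the period midpoint (slope-invariant, better
    conditioned).  Needs at least 3 months.
    """
    if len(series) < 3:
        raise ValueError(f"need >= 3 monthly means, got {len(series)}")
    series = series.sort_index()
    t = np.array([p.year + (p.month - 0.5) / 12.0 for p in series.index])
    t = t - t.mean()
    X = sm.add_constant(t)
    fit = sm.OLS(np.asarray(series, dtype=float), X).fit()
    return TrendResult(
        airbase=airbase,
        period=(str(series.index[0]), str(series.index[-1])),
        slope_per_year=float(fit.params[1]),
        adj_r_squared=float(fit.rsquared_adj),
        df=int(fit.df_resid),
        p_value=float(fit.pvalues[1]),
        n_months=len(series),
    )


def significance_stars(p_value: float) -> str:
    """Conventional footnote stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def trend_table(
    results: Sequence[BSRIResult], airbases: Sequence[str]
) -> pd.DataFrame:
    """Whole-period and last-10-year linear trends for several airbases."""
    rows = []
    for base in airbases:
        series = monthly_means(results, base)
        for label, s in (("whole_period", series), ("last_10_years", last_10_years(series))):
            if len(s) < 3:
                continue
            tr = linear_trend(s, base)
            rows.append(
                {
                    "airbase": base,
                    "period": label,
                    "first_month": tr.period[0],
                    "last_month": tr.period[1],
                    "slope_per_year": tr.slope_per_year,
                    "adj_r2": tr.adj_r_squared,
                    "df": tr.df,
                    "significance": significance_stars(tr.p_value),
                }
            )
    return pd.DataFrame(rows)


def _cyclic_second_difference(n: int) -> np.ndarray:
    """Circular second-difference operator D with (Df)_i = f_{i-1} - 2 f_i + f_{i+1}."""
    D = -2.0 * np.eye(n)
    idx = np.arange(n)
    D[idx, (idx - 1) % n] += 1.0
    D[idx, (idx + 1) % n] += 1.0
    return D


def _smooth(y: np.ndarray, w: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Solve (W + lam * D'D) f = W y; also return the GCV score."""
    n = len(y)
    K = _cyclic_second_difference(n)
    A = np.diag(w) + lam * (K.T @ K)
    B = np.linalg.solve(A, np.diag(w))
    f = B @ np.where(w > 0, y, 0.0)
    obs = w > 0
    n_obs = int(obs.sum())
    resid = (y - f)[obs]
    edf = float(np.trace(B[np.ix_(obs, obs)]))
    denom = max(n_obs - edf, 1e-8)
    gcv = n_obs * float(resid @ resid) / denom**2
    return f, gcv


def seasonal_profile(
    results: Sequence[BSRIResult],
    airbase: str,
    smoothing: float | None = None,
    min_days: int = 30,
) -> SeasonalProfile:
    """Smoothed mean BSRI over day-of-year for one airbase.

    Daily means are computed on the 1–366 grid and smoothed with a cyclic
    second-difference penalty so the profile is periodic (day 366 adjacent
    to day 1).  ``smoothing`` fixes the penalty weight; if ``None`` it is
    chosen by generalized cross-validation over a log-spaced grid.
    """
    rows = [(r.timestamp, r.bsri) for r in results if r.airbase == airbase]
    if not rows:
        raise ValueError(f"no BSRI results for airbase {airbase!r}")
    s = pd.Series(
        [b for _, b in rows], index=pd.DatetimeIndex([t for t, _ in rows])
    )
    daily = s.groupby(s.index.dayofyear).mean()
    if len(daily) < min_days:
        raise ValueError(
            f"need >= {min_days} distinct days of year, got {len(daily)}"
        )
    y = np.zeros(_DAYS_IN_GRID)
    w = np.zeros(_DAYS_IN_GRID)
    y[daily.index.to_numpy() - 1] = daily.to_numpy()
    w[daily.index.to_numpy() - 1] = 1.0

    if smoothing is not None:
        f, _ = _smooth(y, w, smoothing)
        lam = smoothing
    else:
        grid = np.logspace(-2, 6, 17)
        scored = [(lam, *_smooth(y, w, lam)) for lam in grid]
        lam, f, _ = min(scored, key=lambda t: t[2])
    return SeasonalProfile(
        airbase=airbase,
        day_of_year=np.arange(1, _DAYS_IN_GRID + 1),
        bsri=f,
        smoothing=float(lam),
    )
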