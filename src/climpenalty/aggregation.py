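"""Daily-to-seasonal aggregation under completeness filters.

Monitoring records (and, for like-for-like comparison, grid-cell
series) are reduced to monthly means, summer (JJA) means, and June–May
annual means.  A month counts only with more than 6 daily values
(i.e. at least 7 by default), a summer only with at least 2 of its
monthly means, a June–May year only with more than 8 (at least 9)
monthly means, and a site enters the sensitivity analysis only with at
least 11 complete seasonal values within the study years.  All
thresholds are configurable; incomplete windows are dropped, never
imputed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic import StationRecord

__all__ = [
    "daily_mean_temperature",
    "monthly_mean",
    "summer_mean",
    "annual_mean_jun_may",
    "seasonal_values",
    "site_eligibility",
    "station_seasonal_table",
    "grid_seasonal_means",
    "JJA",
]

#: Default summer window (meteorological summer).
JJA = (6, 7, 8)


def daily_mean_temperature(tmax: pd.Series, tmin: pd.Series) -> pd.Series:
    """Daily mean temperature as (tmax + tmin) / 2, missing if either is missing."""
    if len(tmax) != len(tmin) or not tmax.index.equals(tmin.index):
        raise ValueError("tmax and tmin series must share an identical date index")
    return (tmax + tmin) / 2.0


def monthly_mean(daily: pd.Series, min_days: int = 7) -> pd.DataFrame:
    """Monthly means of a daily series with a minimum-day completeness filter.

    Returns one row per observed (year, month) with columns
    ``year, month, value, n_days, complete``; ``value`` is NaN for
    incomplete months.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    s = daily.dropna()
    if s.empty:
        return pd.DataFrame(columns=["year", "month", "value", "n_days", "complete"])
    grp = s.groupby([s.index.year, s.index.month])
    agg = grp.agg(["mean", "count"])
    out = pd.DataFrame(
        {
            "year": [y for y, _ in agg.index],
            "month": [m for _, m in agg.index],
            "value": agg["mean"].to_numpy(),
            "n_days": agg["count"].to_numpy(),
        }
    )
    out["complete"] = out["n_days"] >= min_days
    out.loc[~out["complete"], "value"] = np.nan
    return out.reset_index(drop=True)


def summer_mean(
    monthly: pd.DataFrame,
    min_months: int = 2,
    months: Sequence[int] = JJA,
) -> pd.DataFrame:
    """Summer means per year from a monthly table (equal month weights).

    A summer is reported as complete when at least ``min_months`` of the
    window's monthly means are available.
    """
    if len(months) == 0:
        raise ValueError("summer month set must be nonempty")
    m = monthly[monthly["month"].isin(months) & monthly["complete"]]
    years = sorted(monthly["year"].unique())
    rows = []
    for y in years:
        vals = m.loc[m["year"] == y, "value"].to_numpy(dtype=float)
        n = len(vals)
        complete = n >= min_months
        rows.append(
            {
                "year": int(y),
                "window": "JJA",
                "value": float(np.mean(vals)) if complete else np.nan,
                "n_contributing": n,
                "complete": complete,
            }
        )
    return pd.DataFrame(rows, columns=["year", "window", "value", "n_contributing", "complete"])


def annual_mean_jun_may(monthly: pd.DataFrame, min_months: int = 9) -> pd.DataFrame:
    """June–May annual means labelled by the June year.

    Month *m* of calendar year *y* belongs to label year *y* when
    m >= 6 and to label year *y − 1* otherwise; a label year is complete
    with at least ``min_months`` of its 12 monthly means.
    """
    m = monthly[monthly["complete"]].copy()
    if m.empty:
        return pd.DataFrame(columns=["year", "window", "value", "n_contributing", "complete"])
    m["label_year"] = m["year"].where(m["month"] >= 6, m["year"] - 1)
    rows = []
    for y in sorted(m["label_year"].unique()):
        vals = m.loc[m["label_year"] == y, "value"].to_numpy(dtype=float)
        n = len(vals)
        complete = n >= min_months
        rows.append(
            {
                "year": int(y),
                "window": "ANN_JunMay",
                "value": float(np.mean(vals)) if complete else np.nan,
                "n_contributing": n,
                "complete": complete,
            }
        )
    return pd.DataFrame(rows, columns=["year", "window", "value", "n_contributing", "complete"])


def seasonal_values(
    daily: pd.Series,
    window: str = "JJA",
    min_days: int = 7,
    min_months_summer: int = 2,
    min_months_annual: int = 9,
    months: Sequence[int] = JJA,
) -> pd.DataFrame:
    """Daily series straight to a per-year seasonal table for one window."""
    monthly = monthly_mean(daily, min_days=min_days)
    if window == "JJA":
        return summer_mean(monthly, min_months=min_months_summer, months=months)
    if window == "ANN_JunMay":
        return annual_mean_jun_may(monthly, min_months=min_months_annual)
    raise ValueError(f"unknown window {window!r}")


def site_eligibility(
    seasonal: pd.DataFrame,
    min_years: int = 11,
    years: tuple[int, int] | None = None,
) -> set[str]:
    """Sites with at least ``min_years`` complete seasonal values in the study years.

    ``seasonal`` is a tidy table with columns ``site_id, year, complete``.
    """
    df = seasonal[seasonal["complete"]]
    if years is not None:
        df = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
    counts = df.groupby("site_id")["year"].nunique()
    return set(counts[counts >= min_years].index)


def station_seasonal_table(
    records: Iterable[StationRecord],
    window: str = "JJA",
    min_days: int = 7,
    min_months_summer: int = 2,
    min_months_annual: int = 9,
    months: Sequence[int] = JJA,
) -> pd.DataFrame:
    """Tidy seasonal table (site_id, year, window, value, n_contributing, complete)."""
    frames = []
    for r in records:
        t = seasonal_values(
            r.data,
            window=window,
            min_days=min_days,
            min_months_summer=min_months_summer,
            min_months_annual=min_months_annual,
            months=months,
        )
        t.insert(0, "site_id", r.site_id)
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["site_id", "year", "window", "value", "n_contributing", "complete"]
        )
    return pd.concat(frames, ignore_index=True)


def _grid_monthly(da: xr.DataArray, min_days: int):
    """Vectorised per-cell monthly means and completeness over a daily grid."""
    time = pd.DatetimeIndex(da.time.values)
    periods = time.to_period("M")
    # boundaries of consecutive months along the (sorted) time axis
    codes = periods.year * 12 + periods.month
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    vals = da.values
    finite = np.isfinite(vals)
    sums = np.add.reduceat(np.where(finite, vals, 0.0), starts, axis=0)
    counts = np.add.reduceat(finite.astype(np.int64), starts, axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= min_days, sums / np.maximum(counts, 1), np.nan)
    month_index = periods[starts]
    return month_index, means  # means: (n_months, nlat, nlon)


def grid_seasonal_means(
    da: xr.DataArray,
    window: str = "JJA",
    min_days: int = 7,
    min_months_summer: int = 2,
    min_months_annual: int = 9,
    months: Sequence[int] = JJA,
) -> xr.Dataset:
    """Seasonal means per cell under the same completeness filters as stations.

    Returns a Dataset with ``value`` (year, lat, lon), ``n_contributing``
    and ``complete``; incomplete cell-years carry NaN.
    """
    if window == "JJA":
        keep_months, min_months = tuple(months), min_months_summer
    elif window == "ANN_JunMay":
        keep_months, min_months = tuple(range(1, 13)), min_months_annual
    else:
        raise ValueError(f"unknown window {window!r}")

    month_index, means = _grid_monthly(da, min_days)
    myear = month_index.year.to_numpy()
    mmonth = month_index.month.to_numpy()
    if window == "JJA":
        label = myear
    else:
        label = np.where(mmonth >= 6, myear, myear - 1)
    in_window = np.isin(mmonth, keep_months)

    years = np.unique(label[in_window])
    nlat, nlon = means.shape[1:]
    out_vals = np.full((len(years), nlat, nlon), np.nan)
    out_n = np.zeros((len(years), nlat, nlon), dtype=np.int64)
    for k, y in enumerate(years):
        sel = in_window & (label == y)
        block = means[sel]  # (n_sel_months, nlat, nlon)
        avail = np.isfinite(block)
        n = avail.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, np.nansum(block, axis=0) / np.maximum(n, 1), np.nan)
        out_n[k] = n
        out_vals[k] = np.where(n >= min_months, mean, np.nan)

    complete = out_n >= min_months
    return xr.Dataset(
        {
            "value": (("year", "lat", "lon"), out_vals, dict(da.attrs)),
            "n_contributing": (("year", "lat", "lon"), out_n),
            "complete": (("year", "lat", "lon"), complete),
        },
        coords={"year": years, "lat": da.lat.values, "lon": da.lon.values},
        attrs={"window": window},
    )
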