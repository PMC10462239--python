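"""Climate-penalty slope estimation: m(Δpollutant) per site and per cell.

The penalty statistic is the slope of the ordinary least-squares fit of
detrended seasonal pollutant anomalies on detrended summer-temperature
anomalies.  Detrending is the OLS residual of a value-on-year fit,
which removes the long-term mean and the linear (emission-driven) trend
in a single step; by the Frisch–Waugh–Lovell theorem the resulting
slope equals the temperature coefficient of the joint regression of
raw values on (temperature, year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .synthetic import StationRecord

__all__ = [
    "AnomalySeries",
    "SensitivityEstimate",
    "ColocatedPair",
    "detrend",
    "sensitivity_slope",
    "gridwise_sensitivity",
    "colocate_station_pairs",
    "extract_colocated_grid",
    "prepare_exposure_map",
    "haversine_km",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class AnomalySeries:
    """Detrended interannual anomalies of one unit (site or cell)."""

    unit_id: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class SensitivityEstimate:
    """OLS slope of pollutant anomalies on temperature anomalies with uncertainty."""

    unit_id: str
    slope: float
    intercept: float
    se: float
    p_value: float
    n_years: int
    r: float
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < self.alpha)


def detrend(years, values, unit_id: str = "") -> AnomalySeries:
    """OLS residuals of value on year: mean- and trend-free anomalies.

    Pairs with missing values are dropped; at least 3 distinct years are
    required.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape:
        raise ValueError("years and values must have the same length")
    keep = np.isfinite(values) & np.isfinite(years)
    years, values = years[keep], values[keep]
    if len(np.unique(years)) < 3:
        raise ValueError("detrending needs at least 3 distinct years")
    yc = years - years.mean()
    denom = (yc * yc).sum()
    slope = (yc * values).sum() / denom
    resid = values - values.mean() - slope * yc
    return AnomalySeries(unit_id=unit_id, years=years.astype(int), values=resid)


def sensitivity_slope(
    anom_t: AnomalySeries, anom_y: AnomalySeries, alpha: float = 0.05
) -> SensitivityEstimate:
    """Slope of pollutant anomalies on temperature anomalies (two-sided t test).

    Years present in only one series, or with a missing member, are
    dropped listwise.  A temperature series with zero variance yields a
    flagged degenerate estimate with undefined slope.
    """
    ty = pd.Series(anom_t.values, index=anom_t.years)
    yy = pd.Series(anom_y.values, index=anom_y.years)
    common = ty.index.intersection(yy.index)
    x = ty.loc[common].to_numpy()
    y = yy.loc[common].to_numpy()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    uid = anom_y.unit_id or anom_t.unit_id
    if n < 3:
        raise ValueError(f"need at least 3 common years, got {n}")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx <= 0:
        return SensitivityEstimate(uid, np.nan, np.nan, np.nan, np.nan, n, np.nan,
                                   alpha=alpha, degenerate=True)
    res = stats.linregress(x, y)
    return SensitivityEstimate(
        unit_id=uid,
        slope=float(res.slope),
        intercept=float(res.intercept),
        se=float(res.stderr),
        p_value=float(res.pvalue),
        n_years=n,
        r=float(res.rvalue),
        alpha=alpha,
    )


def _masked_detrend(values: np.ndarray, years: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-cell OLS residuals on year within a validity mask, vectorised.

    ``values``: (n_years, ...); ``valid``: same shape boolean.  Cells
    with fewer than 3 valid years come back all-NaN.
    """
    w = valid.astype(float)
    yr = years.astype(float).reshape((-1,) + (1,) * (values.ndim - 1))
    n = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = (w * yr).sum(axis=0) / n
        vbar = np.nansum(np.where(valid, values, 0.0), axis=0) / n
        yc = np.where(valid, yr - ybar, 0.0)
        syy = (yc * yc).sum(axis=0)
        sxv = (yc * np.where(valid, values - vbar, 0.0)).sum(axis=0)
        slope = sxv / syy
        resid = np.where(valid, values - vbar - slope * yc, np.nan)
    resid = np.where((n >= 3) & (syy > 0), resid, np.nan)
    return resid


def gridwise_sensitivity(
    pollutant_seasonal: xr.Dataset | xr.DataArray,
    temp_seasonal: xr.Dataset | xr.DataArray,
    alpha: float = 0.05,
    min_years: int = 3,
) -> xr.Dataset:
    """Per-cell detrended sensitivity map from seasonal-mean grids.

    Both inputs carry a ``(year, lat, lon)`` ``value`` array (or are
    such arrays); cells with fewer than ``min_years`` complete common
    years are missing in the output.
    """
    p = pollutant_seasonal["value"] if isinstance(pollutant_seasonal, xr.Dataset) else pollutant_seasonal
    t = temp_seasonal["value"] if isinstance(temp_seasonal, xr.Dataset) else temp_seasonal
    if (p.sizes != t.sizes) or (not np.array_equal(p.year.values, t.year.values)):
        raise ValueError("pollutant and temperature grids are not aligned")
    if not (np.array_equal(p.lat.values, t.lat.values) and np.array_equal(p.lon.values, t.lon.values)):
        raise ValueError("pollutant and temperature grids are not aligned")

    years = p.year.values.astype(int)
    pv, tv = p.values, t.values
    valid = np.isfinite(pv) & np.isfinite(tv)
    n = valid.sum(axis=0)

    dp = _masked_detrend(pv, years, valid)
    dt = _masked_detrend(tv, years, valid)

    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = np.nansum(dt * dt, axis=0)
        sxy = np.nansum(dt * dp, axis=0)
        syy = np.nansum(dp * dp, axis=0)
        slope = sxy / sxx
        rss = syy - slope * sxy
        dof = n - 2
        se = np.sqrt(np.maximum(rss, 0.0) / np.maximum(dof, 1) / sxx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat = slope / se
            r = sxy / np.sqrt(sxx * syy)
    pval = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(dof, 1))
    bad = (n < max(min_years, 3)) | ~np.isfinite(slope)
    for arr in (slope, se, r):
        arr[bad] = np.nan
    pval = np.where(bad, np.nan, pval)

    return xr.Dataset(
        {
            "slope": (("lat", "lon"), slope),
            "p_value": (("lat", "lon"), pval),
            "se": (("lat", "lon"), se),
            "r": (("lat", "lon"), r),
            "n_years": (("lat", "lon"), n.astype(np.int32)),
        },
        coords={"lat": p.lat.values, "lon": p.lon.values},
        attrs={
            "alpha": alpha,
            "window": str(pollutant_seasonal.attrs.get("window", "")),
            "variable": str(p.attrs.get("variable", "")),
            "units_per_degC": str(p.attrs.get("units", "")) + "/degC",
        },
    )


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km on a sphere (WGS84-as-sphere, R=6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float), np.asarray(lon1, float),
                                              np.asarray(lat2, float), np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ColocatedPair:
    """A pollutant site paired with the datewise mean of in-radius temperature stations."""

    site: StationRecord
    temperature: pd.Series
    n_temp_stations: int


def colocate_station_pairs(
    pollutant_sites: list[StationRecord],
    temp_stations: list[StationRecord],
    radius_km: float = 30.0,
) -> list[ColocatedPair]:
    """Pair each pollutant site with the average of temperature stations within radius.

    Temperature stations within the great-circle radius are averaged
    datewise into a single series; pollutant sites with no in-radius
    station are dropped.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if not temp_stations:
        return []
    tlat = np.array([t.latitude for t in temp_stations])
    tlon = np.array([t.longitude for t in temp_stations])
    pairs = []
    for site in pollutant_sites:
        d = haversine_km(site.latitude, site.longitude, tlat, tlon)
        idx = np.flatnonzero(d <= radius_km)
        if len(idx) == 0:
            continue
        merged = pd.concat([temp_stations[i].data for i in idx], axis=1)
        pairs.append(ColocatedPair(site=site, temperature=merged.mean(axis=1), n_temp_stations=len(idx)))
    return pairs


def extract_colocated_grid(
    grid: xr.DataArray,
    sites: list[StationRecord],
    radius_km: float = 5.0,
) -> dict[str, pd.Series]:
    """Grid-cell series co-located with each site (cells within radius averaged).

    Sites with no cell center inside the radius are dropped with a
    warning.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lat2d, lon2d = np.meshgrid(grid.lat.values, grid.lon.values, indexing="ij")
    time = pd.DatetimeIndex(grid.time.values)
    out: dict[str, pd.Series] = {}
    for site in sites:
        d = haversine_km(site.latitude, site.longitude, lat2d, lon2d)
        ii, jj = np.nonzero(d <= radius_km)
        if len(ii) == 0:
            warnings.warn(f"site {site.site_id}: no grid cell within {radius_km} km; dropped")
            continue
        series = grid.values[:, ii, jj].mean(axis=1)
        out[site.site_id] = pd.Series(series, index=time)
    return out


def prepare_exposure_map(sensitivity: xr.Dataset) -> xr.Dataset:
    """Clamp negative slopes to zero for exposure analysis.

    Statistically insignificant negative sensitivities are treated as
    "no climate penalty"; p-values and missingness are preserved, and
    the operation is idempotent.
    """
    out = sensitivity.copy()
    out["slope"] = out["slope"].clip(min=0.0)
    return out
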