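"""Synthetic gridded and station inputs with known ground truth.

Every downstream stage of the climate-penalty pipeline (aggregation,
slope estimation, regional pooling, exposure, speciation) is exercised
on data produced here, so the generative model deliberately *inverts*
the analysis model: daily pollutant concentrations are built as

    c(cell, day of year y) = baseline(cell)
                           + trend(cell) * (y - y0)
                           + beta(cell) * dT(cell, y)
                           + eps(cell, day)

where ``dT`` is a zero-mean, spatially correlated summer temperature
anomaly drawn once per year and ``eps`` is iid daily observation noise.
With zero noise, regressing detrended seasonal-mean pollutant anomalies
on detrended seasonal-mean temperature anomalies recovers ``beta``
exactly, which is the self-consistency contract the tests rely on.

Years here are "pollution years": the year labelled *y* runs June of
*y* through May of *y+1*, so both the JJA summer window and the
June–May annual window of every study year are complete.  The daily
time axis therefore spans Jun 1 of the first year to May 31 after the
last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

__all__ = [
    "SPECIES",
    "TruthConfig",
    "StationRecord",
    "make_truth",
    "simulate_fields",
    "sample_stations",
    "simulate_population",
    "make_region_mask",
    "daily_sd_for_seasonal_sd",
    "write_grid",
    "read_grid",
    "write_stations",
    "read_stations",
    "write_truth",
    "read_truth",
]

#: PM2.5 components carried by the generator.  "oc" is organic carbon
#: mass; the analysis converts it to organic aerosol with a 2.1 factor.
SPECIES = ("sulfate", "nitrate", "ammonium", "oc", "ec")

# Mean number of days in the JJA months; used to translate a target
# seasonal-mean noise SD into the daily noise SD that produces it.
_DAYS_IN_MONTH = {6: 30, 7: 31, 8: 31, 9: 30}


def daily_sd_for_seasonal_sd(seasonal_sd: float, months: Sequence[int] = (6, 7, 8)) -> float:
    """Daily iid noise SD whose season-mean (mean of monthly means) has SD ``seasonal_sd``.

    The seasonal value is the equal-weight mean of the monthly means, so
    Var(season) = sd_daily**2 * sum(1/n_days_m) / n_months**2.
    """
    inv = sum(1.0 / _DAYS_IN_MONTH[m] for m in months)
    return float(seasonal_sd * len(months) / np.sqrt(inv))


@dataclass
class StationRecord:
    """One monitoring site's dated measurements of one variable."""

    site_id: str
    latitude: float
    longitude: float
    variable: str
    units: str
    data: pd.Series  # DatetimeIndex -> float

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError(f"duplicate dates in station {self.site_id}")
        finite = np.isfinite(self.data.to_numpy(dtype=float))
        present = self.data.notna().to_numpy()
        if not np.all(finite[present]):
            raise ValueError(f"non-finite values in station {self.site_id}")


@dataclass
class TruthConfig:
    """Ground-truth parameters of the synthetic study domain.

    Per-cell fields are 2-D arrays of shape ``(n_lat, n_lon)``.  Units:
    betas in pollutant-units per degree C (ug/m3/degC for PM2.5 and its
    species, ppb/degC for O3), trends in units per year, baselines in
    pollutant units, ``temp_anom_sd`` in degC, ``spatial_corr_len`` in
    grid cells.
    """

    seed: int
    n_lat: int
    n_lon: int
    lat0: float
    lon0: float
    cell_deg: float
    year_start: int
    year_end: int
    beta_pm: np.ndarray
    beta_o3: np.ndarray
    trend_pm: np.ndarray
    trend_o3: np.ndarray
    baseline_pm: np.ndarray
    baseline_o3: np.ndarray
    noise_sd_daily: Mapping[str, float]
    temp_anom_sd: float
    spatial_corr_len: float
    species_shares: Mapping[str, float]
    species_beta: Mapping[str, np.ndarray]
    # Period-contrast ("decadal-shift") scenarios: betas used from
    # shift_year onward; None means the betas are constant in time.
    beta_pm_late: np.ndarray | None = None
    beta_o3_late: np.ndarray | None = None
    shift_year: int = 2010
    # Provenance: arguments that rebuild this config via make_truth().
    scenario: str = "flat"
    scenario_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be positive")
        if self.year_end - self.year_start < 1:
            raise ValueError("year range must span at least 2 years")
        total = 0.0
        for name, share in self.species_shares.items():
            if not (0.0 <= share <= 1.0):
                raise ValueError(f"species share {name}={share} outside [0, 1]")
            total += share
        if total > 1.0 + 1e-12:
            raise ValueError(f"species shares sum to {total} > 1")
        shape = (self.n_lat, self.n_lon)
        for attr in ("beta_pm", "beta_o3", "trend_pm", "trend_o3", "baseline_pm", "baseline_o3"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{attr} has shape {arr.shape}, expected {shape}")
            setattr(self, attr, arr)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cell_deg * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cell_deg * np.arange(self.n_lon)


def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """Spatially correlated field with zero mean and unit SD.

    White noise smoothed with a Gaussian kernel of width ``corr_len``
    cells, then standardised over the grid.  The exact covariance form
    is a generator choice, not a constraint of the analysis.
    """
    white = rng.standard_normal(shape)
    if corr_len > 0:
        f = gaussian_filter(white, sigma=corr_len, mode="reflect")
    else:
        f = white
    sd = f.std()
    if sd == 0:  # pragma: no cover - degenerate 1x1 grids only
        return np.zeros(shape)
    return (f - f.mean()) / sd


_DEFAULT_SHARES = {"sulfate": 0.25, "nitrate": 0.08, "ammonium": 0.10, "oc": 0.12, "ec": 0.05}


def make_truth(
    seed: int,
    shape: tuple[int, int] = (20, 30),
    years: tuple[int, int] = (2000, 2016),
    scenario: str = "flat",
    **params: float,
) -> TruthConfig:
    """Build a :class:`TruthConfig` for a named scenario.

    Scenarios
    ---------
    ``flat``
        Constant betas everywhere (``beta_pm``, ``beta_o3``).
    ``two-region``
        Contrasting betas in the western vs eastern half
        (``beta_west``, ``beta_east`` scale both pollutants).
    ``decadal-shift``
        Constant betas that change at ``shift_year`` (default 2010):
        ``beta1`` before, ``beta2`` after, for both pollutants.
    ``random``
        Smooth random beta fields mapped into [``beta_lo``, ``beta_hi``]
        (default [0, 2]) through a logistic squash of a correlated
        Gaussian field; deterministic per seed.

    All remaining generator parameters (baselines, trends, noise levels,
    anomaly SD, correlation length, species shares) take the package
    defaults unless overridden via keyword arguments.
    """
    n_lat, n_lon = shape
    if n_lat < 4 or n_lon < 4:
        raise ValueError(f"grid shape {shape} too small; need at least 4x4")
    y0, y1 = years
    if y1 - y0 < 2:
        raise ValueError(f"year range {years} must span at least 3 years")

    known = {
        "beta_pm", "beta_o3", "beta_west", "beta_east", "beta1", "beta2",
        "beta_lo", "beta_hi", "shift_year", "baseline_pm", "baseline_o3",
        "trend_pm", "trend_o3", "noise_seasonal_sd", "temp_anom_sd",
        "spatial_corr_len", "lat0", "lon0", "cell_deg",
    }
    unknown = set(params) - known
    if unknown:
        raise ValueError(f"unknown scenario parameters: {sorted(unknown)}")

    p = dict(params)
    lat0 = p.pop("lat0", 32.0)
    lon0 = p.pop("lon0", -115.0)
    cell_deg = p.pop("cell_deg", 0.25)
    baseline_pm = p.pop("baseline_pm", 10.0)
    baseline_o3 = p.pop("baseline_o3", 45.0)
    trend_pm = p.pop("trend_pm", -0.15)
    trend_o3 = p.pop("trend_o3", -0.25)
    noise_seasonal_sd = p.pop("noise_seasonal_sd", 0.5)
    temp_anom_sd = p.pop("temp_anom_sd", 0.8)
    spatial_corr_len = p.pop("spatial_corr_len", 3.0)
    shift_year = int(p.pop("shift_year", 2010))

    const = lambda v: np.full(shape, float(v))  # noqa: E731
    beta_pm_late = beta_o3_late = None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE7A]))

    if scenario == "flat":
        beta_pm = const(p.pop("beta_pm", 1.0))
        beta_o3 = const(p.pop("beta_o3", 3.0))
    elif scenario == "two-region":
        hi = float(p.pop("beta_west", 2.0))
        lo = float(p.pop("beta_east", 0.5))
        west = np.arange(n_lon) < n_lon // 2
        beta_pm = np.where(west[None, :], hi, lo) * np.ones(shape)
        beta_o3 = 2.0 * beta_pm
    elif scenario == "decadal-shift":
        b1 = float(p.pop("beta1", 2.0))
        b2 = float(p.pop("beta2", 0.5))
        beta_pm = const(b1)
        beta_pm_late = const(b2)
        beta_o3 = const(2.0 * b1)
        beta_o3_late = const(2.0 * b2)
    elif scenario == "random":
        lo = float(p.pop("beta_lo", 0.0))
        hi = float(p.pop("beta_hi", 2.0))
        z = _smooth_standard_field(rng, shape, spatial_corr_len)
        beta_pm = lo + (hi - lo) / (1.0 + np.exp(-z))
        z2 = _smooth_standard_field(rng, shape, spatial_corr_len)
        beta_o3 = 3.0 * (lo + (hi - lo) / (1.0 + np.exp(-z2))) / max(hi, 1e-12)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    noise_daily = daily_sd_for_seasonal_sd(noise_seasonal_sd)
    shares = dict(_DEFAULT_SHARES)
    # Species betas default to share-proportional splits of the total
    # PM2.5 beta, so species exactly partition the signal.
    species_beta = {s: shares[s] * beta_pm for s in SPECIES}

    return TruthConfig(
        seed=int(seed),
        n_lat=n_lat,
        n_lon=n_lon,
        lat0=lat0,
        lon0=lon0,
        cell_deg=cell_deg,
        year_start=y0,
        year_end=y1,
        beta_pm=beta_pm,
        beta_o3=beta_o3,
        beta_pm_late=beta_pm_late,
        beta_o3_late=beta_o3_late,
        shift_year=shift_year,
        trend_pm=const(trend_pm),
        trend_o3=const(trend_o3),
        baseline_pm=const(baseline_pm),
        baseline_o3=const(baseline_o3),
        noise_sd_daily={"pm25": noise_daily, "o3": noise_daily},
        temp_anom_sd=temp_anom_sd,
        spatial_corr_len=spatial_corr_len,
        species_shares=shares,
        species_beta=species_beta,
        scenario=scenario,
        scenario_params={k: float(v) for k, v in params.items()},
    )


def _time_axis(truth: TruthConfig) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{truth.year_start}-06-01", f"{truth.year_end + 1}-05-31", freq="D"
    )


def pollution_year(index: pd.DatetimeIndex) -> np.ndarray:
    """Anomaly-year label of each date: June–May windows labelled by their June."""
    return index.year.to_numpy() - (index.month.to_numpy() < 6).astype(int)


def draw_temp_anomalies(truth: TruthConfig) -> np.ndarray:
    """Per-year spatially correlated summer temperature anomalies, (n_years, n_lat, n_lon).

    Each yearly field is standardised over the grid and scaled to
    ``temp_anom_sd``; draws are independent across years and
    deterministic for a fixed truth seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x7E3B]))
    fields = [
        _smooth_standard_field(rng, (truth.n_lat, truth.n_lon), truth.spatial_corr_len)
        for _ in truth.years
    ]
    return truth.temp_anom_sd * np.stack(fields)


def _beta_by_year(truth: TruthConfig, beta: np.ndarray, beta_late: np.ndarray | None) -> np.ndarray:
    out = np.broadcast_to(beta, (len(truth.years), truth.n_lat, truth.n_lon)).copy()
    if beta_late is not None:
        out[truth.years >= truth.shift_year] = beta_late
    return out


def _as_da(values: np.ndarray, time: pd.DatetimeIndex, truth: TruthConfig, name: str, units: str) -> xr.DataArray:
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": time, "lat": truth.lats, "lon": truth.lons},
        name=name,
        attrs={"units": units, "variable": name},
    )


def simulate_fields(
    truth: TruthConfig,
    variables: Sequence[str] = ("temperature", "pm25", "o3", "species"),
) -> dict[str, xr.DataArray]:
    """Simulate daily gridded fields for the configured study domain.

    Returns a dict with keys among ``tmax``, ``tmin``, ``pm25``, ``o3``,
    the species names, and ``residual`` (total PM2.5 minus the summed
    species), depending on ``variables``.  Restricting ``variables``
    skips the corresponding noise draws without perturbing the draws of
    the variables that are generated: every variable consumes its own
    deterministic seed sub-stream.
    """
    time = _time_axis(truth)
    py = pollution_year(time)
    yidx = py - truth.year_start
    dt = draw_temp_anomalies(truth)  # (n_years, nlat, nlon)
    dt_daily = dt[yidx]  # (T, nlat, nlon)
    yrs_daily = yidx.astype(float)[:, None, None]

    out: dict[str, xr.DataArray] = {}

    if "temperature" in variables:
        # seasonal cycle keyed to (month, day) on a fixed 365-day calendar:
        # identical every year, so summer means differ across years only
        # through the drawn anomalies (leap days repeat Feb 28's value)
        cum = np.r_[0, np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])]
        doy = cum[time.month.to_numpy() - 1] + np.minimum(time.day.to_numpy(), 28 + 3 * (time.month.to_numpy() != 2))
        seasonal = 15.0 + 10.0 * np.cos(2 * np.pi * (doy - 196) / 365.0)
        tmean = seasonal[:, None, None] + dt_daily
        out["tmax"] = _as_da(tmean + 5.0, time, truth, "tmax", "degC")
        out["tmin"] = _as_da(tmean - 5.0, time, truth, "tmin", "degC")

    need_pm = "pm25" in variables or "species" in variables
    if need_pm:
        rng_pm = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x901]))
        eps_pm = rng_pm.standard_normal((len(time), truth.n_lat, truth.n_lon))
        eps_pm *= truth.noise_sd_daily["pm25"]
        beta_pm_d = _beta_by_year(truth, truth.beta_pm, truth.beta_pm_late)[yidx]
        det_pm = truth.baseline_pm + truth.trend_pm * yrs_daily
        pm = det_pm + beta_pm_d * dt_daily + eps_pm
        if "pm25" in variables:
            out["pm25"] = _as_da(pm, time, truth, "pm25", "ug/m3")

    if "o3" in variables:
        rng_o3 = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x902]))
        eps_o3 = rng_o3.standard_normal((len(time), truth.n_lat, truth.n_lon))
        eps_o3 *= truth.noise_sd_daily["o3"]
        beta_o3_d = _beta_by_year(truth, truth.beta_o3, truth.beta_o3_late)[yidx]
        out["o3"] = _as_da(
            truth.baseline_o3 + truth.trend_o3 * yrs_daily + beta_o3_d * dt_daily + eps_o3,
            time, truth, "o3", "ppb",
        )

    if "species" in variables:
        total_species = np.zeros_like(pm)
        for s in SPECIES:
            share = truth.species_shares[s]
            beta_s = np.asarray(truth.species_beta[s])
            vals = share * (det_pm + eps_pm) + beta_s[None, :, :] * dt_daily
            total_species += vals
            out[s] = _as_da(vals, time, truth, s, "ug/m3")
        out["residual"] = _as_da(pm - total_species, time, truth, "residual", "ug/m3")

    return out


def sample_stations(
    fields: xr.DataArray,
    n_sites: int,
    sampling_interval_days: int = 3,
    miss_rate: float = 0.0,
    seed: int = 0,
) -> list[StationRecord]:
    """Sparse station network sampled from a gridded daily field.

    Sites sit at distinct cell centers; records are scheduled every
    ``sampling_interval_days`` (the 1-in-3-day sampling typical of
    filter-based monitors) with independent dropout at ``miss_rate``.
    """
    if not (0.0 <= miss_rate < 1.0):
        raise ValueError("miss_rate must be in [0, 1)")
    n_lat, n_lon = fields.sizes["lat"], fields.sizes["lon"]
    n_cells = n_lat * n_lon
    if n_sites > n_cells:
        raise ValueError(f"n_sites={n_sites} exceeds number of grid cells {n_cells}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57A7]))
    flat = rng.choice(n_cells, size=n_sites, replace=False)
    ii, jj = np.unravel_index(flat, (n_lat, n_lon))
    time = pd.DatetimeIndex(fields.time.values)
    sched = np.arange(0, len(time), sampling_interval_days)
    records = []
    var = str(fields.attrs.get("variable", fields.name or "value"))
    units = str(fields.attrs.get("units", ""))
    vals_all = fields.values  # (T, lat, lon)
    for k, (i, j) in enumerate(zip(ii, jj)):
        keep = sched[rng.random(len(sched)) >= miss_rate]
        series = pd.Series(vals_all[keep, i, j], index=time[keep])
        records.append(
            StationRecord(
                site_id=f"S{k:04d}",
                latitude=float(fields.lat.values[i]),
                longitude=float(fields.lon.values[j]),
                variable=var,
                units=units,
                data=series,
            )
        )
    return records


def simulate_population(truth: TruthConfig, n_clusters: int = 5, seed: int = 0) -> xr.Dataset:
    """Clustered population grid (density in people/km2, count in people).

    Log-normal cluster peak densities on a sparse rural background; by
    construction at least one cell reaches the 400 people/km2 urban
    cutoff and at least one stays below it, so urban/nonurban
    stratification is always exercised.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0B]))
    lats, lons = truth.lats, truth.lons
    ii = rng.integers(0, truth.n_lat, n_clusters)
    jj = rng.integers(0, truth.n_lon, n_clusters)
    peaks = rng.lognormal(mean=np.log(800.0), sigma=0.8, size=n_clusters)
    gi, gj = np.meshgrid(np.arange(truth.n_lat), np.arange(truth.n_lon), indexing="ij")
    density = np.full((truth.n_lat, truth.n_lon), 2.0)
    sigma = 2.0  # cluster spread in cells
    for i, j, pk in zip(ii, jj, peaks):
        d2 = (gi - i) ** 2 + (gj - j) ** 2
        density = density + pk * np.exp(-d2 / (2 * sigma**2))
    if density.max() < 400.0:
        density *= 800.0 / density.max()
    cell_area = np.broadcast_to(
        (truth.cell_deg * 111.32) ** 2 * np.cos(np.deg2rad(lats))[:, None],
        density.shape,
    ).copy()
    count = density * cell_area
    return xr.Dataset(
        {
            "density": (("lat", "lon"), density, {"units": "people/km2"}),
            "count": (("lat", "lon"), count, {"units": "people"}),
            "cell_area": (("lat", "lon"), cell_area, {"units": "km2"}),
        },
        coords={"lat": lats, "lon": lons},
    )


REGION_CODES = {1: "Southeast", 2: "Northeast", 3: "West", 4: "Central"}


def make_region_mask(truth: TruthConfig) -> xr.DataArray:
    """Four-region mask over the synthetic domain (West/Central/Northeast/Southeast).

    Longitude thirds define West and Central; the eastern third splits
    at the latitude midpoint into Northeast and Southeast — a stylised
    stand-in for the four-region division of the contiguous US.
    """
    lats, lons = truth.lats, truth.lons
    x = (lons - lons[0]) / max(lons[-1] - lons[0], 1e-12)
    mid_lat = 0.5 * (lats[0] + lats[-1])
    code = np.empty((truth.n_lat, truth.n_lon), dtype=np.int32)
    for j, xv in enumerate(x):
        if xv < 1 / 3:
            code[:, j] = 3
        elif xv < 2 / 3:
            code[:, j] = 4
        else:
            code[:, j] = np.where(lats >= mid_lat, 2, 1)
    return xr.DataArray(
        code,
        dims=("lat", "lon"),
        coords={"lat": lats, "lon": lons},
        name="region",
        attrs={"codes": ";".join(f"{k}={v}" for k, v in REGION_CODES.items())},
    )


# ---------------------------------------------------------------------------
# External interfaces: CF-style NetCDF for grids, tidy CSV for stations,
# a flat key=value text file for the truth configuration.

def write_grid(da: xr.DataArray | xr.Dataset, path) -> None:
    ds = da.to_dataset(name=da.name or "value") if isinstance(da, xr.DataArray) else da
    ds.to_netcdf(path, engine="scipy")


def read_grid(path, variable: str | None = None):
    ds = xr.load_dataset(path, engine="scipy")
    if variable is not None:
        return ds[variable]
    if len(ds.data_vars) == 1:
        return ds[next(iter(ds.data_vars))]
    return ds


_STATION_COLUMNS = ["site_id", "lat", "lon", "date", "variable", "units", "value"]


def write_stations(records: Sequence[StationRecord], path) -> None:
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "site_id": r.site_id,
                    "lat": r.latitude,
                    "lon": r.longitude,
                    "date": r.data.index.strftime("%Y-%m-%d"),
                    "variable": r.variable,
                    "units": r.units,
                    "value": r.data.to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True)[_STATION_COLUMNS].to_csv(path, index=False)


def read_stations(path) -> list[StationRecord]:
    df = pd.read_csv(path, parse_dates=["date"])
    records = []
    for (sid, var), g in df.groupby(["site_id", "variable"], sort=True):
        records.append(
            StationRecord(
                site_id=str(sid),
                latitude=float(g["lat"].iloc[0]),
                longitude=float(g["lon"].iloc[0]),
                variable=str(var),
                units=str(g["units"].iloc[0]),
                data=pd.Series(g["value"].to_numpy(), index=pd.DatetimeIndex(g["date"])),
            )
        )
    return records


def write_truth(truth: TruthConfig, path) -> None:
    """Serialise the make_truth() arguments; fields rebuild deterministically."""
    lines = [
        f"seed = {truth.seed}",
        f"n_lat = {truth.n_lat}",
        f"n_lon = {truth.n_lon}",
        f"year_start = {truth.year_start}",
        f"year_end = {truth.year_end}",
        f"scenario = {truth.scenario}",
    ]
    for k, v in truth.scenario_params.items():
        lines.append(f"param.{k} = {v!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth(path) -> TruthConfig:
    raw: dict[str, str] = {}
    params: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key.startswith("param."):
                params[key[6:]] = float(val)
            else:
                raw[key] = val
    return make_truth(
        seed=int(raw["seed"]),
        shape=(int(raw["n_lat"]), int(raw["n_lon"])),
        years=(int(raw["year_start"]), int(raw["year_end"])),
        scenario=raw["scenario"],
        **params,
    )
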