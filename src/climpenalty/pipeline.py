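"""End-to-end orchestration: simulate → aggregate → estimate → regional → exposure → species.

Every stage logs record counts and attrition into a
:class:`RunReport`; all tabular outputs are CSV and all gridded
outputs NetCDF under the configured output directory.  A fixed
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .aggregation import grid_seasonal_means, station_seasonal_table, site_eligibility
from .config import RunConfig
from .estimation import (
    colocate_station_pairs,
    detrend,
    gridwise_sensitivity,
    prepare_exposure_map,
    sensitivity_slope,
)
from .exposure import (
    align_population,
    derive_threshold,
    exposure_distribution,
    stratified_sensitivity,
    urban_mask,
)
from .regional import (
    bootstrap_regional,
    moving_window_sensitivity,
    period_anomalies,
    period_change,
    pool_region_anomalies,
)
from .species import component_sensitivity, contribution_fractions
from .synthetic import (
    REGION_CODES,
    StationRecord,
    make_region_mask,
    make_truth,
    sample_stations,
    simulate_fields,
    simulate_population,
    write_grid,
    write_stations,
    write_truth,
)

__all__ = ["RunReport", "StageRecord", "run_pipeline"]

log = logging.getLogger("climpenalty")

WINDOWS = (("pm25", "JJA"), ("pm25", "ANN_JunMay"), ("o3", "JJA"))


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_dropped: int
    n_out: int
    details: dict = field(default_factory=dict)


@dataclass
class RunReport:
    seed: int
    version: str
    config: dict
    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_dropped: int, details: dict | None = None) -> None:
        if any(s.name == name for s in self.stages):
            raise RuntimeError(f"stage {name} recorded twice")
        self.stages.append(StageRecord(name, n_in, n_dropped, n_in - n_dropped, details or {}))
        log.info("stage %-10s in=%d dropped=%d out=%d", name, n_in, n_dropped, n_in - n_dropped)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig, through: str | None = None) -> RunReport:
    """Execute the stages in order, writing outputs under ``config.outdir``.

    ``through`` stops after the named stage ("simulate", "aggregate",
    "estimate", "regional", "exposure" or "species"); earlier stages
    always run since each stage consumes its predecessors in memory.
    """
    config.validate()
    if through is not None and through not in ("simulate", "aggregate", "estimate",
                                               "regional", "exposure", "species"):
        raise ValueError(f"unknown stage {through!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__,
                       config=dataclasses.asdict(config))

    def finished(name: str) -> bool:
        return through is not None and name == through

    stage = "simulate"
    try:
        # ---- simulate -------------------------------------------------
        truth = make_truth(
            seed=config.seed,
            shape=(config.n_lat, config.n_lon),
            years=(config.year_start, config.year_end),
            scenario=config.scenario,
        )
        fields = simulate_fields(truth)
        pop = simulate_population(truth, n_clusters=config.n_pop_clusters, seed=config.seed)
        mask = make_region_mask(truth)
        write_truth(truth, outdir / "truth.cfg")
        write_grid(pop, outdir / "population.nc")
        write_grid(mask.to_dataset(name="region"), outdir / "regions.nc")
        n_cells = config.n_lat * config.n_lon
        report.add(stage, n_cells, 0, {"variables": sorted(fields)})

        # station networks sampled from the gridded truth
        tmean = (fields["tmax"] + fields["tmin"]) / 2.0
        tmean.attrs.update(units="degC", variable="temperature")
        pm_sites = sample_stations(fields["pm25"], config.n_sites,
                                   config.sampling_interval_days, config.miss_rate,
                                   seed=config.seed)
        o3_sites = sample_stations(fields["o3"], config.n_sites,
                                   config.sampling_interval_days, config.miss_rate,
                                   seed=config.seed + 1)
        temp_sites = sample_stations(tmean, config.n_temp_stations, 1, 0.0,
                                     seed=config.seed + 2)
        write_stations(pm_sites, outdir / "stations_pm25.csv")
        write_stations(o3_sites, outdir / "stations_o3.csv")
        write_stations(temp_sites, outdir / "stations_temp.csv")
        if finished("simulate"):
            (outdir / "report.json").write_text(report.to_json())
            return report

        # ---- aggregate ------------------------------------------------
        stage = "aggregate"
        agg_kw = dict(
            min_days=config.min_days_month,
            min_months_summer=config.min_months_summer,
            min_months_annual=config.min_months_annual,
            months=config.summer_months,
        )
        seasonal = {}
        for var, window in WINDOWS:
            seasonal[(var, window)] = grid_seasonal_means(fields[var], window=window, **agg_kw)
        temp_jja = grid_seasonal_means(tmean, window="JJA", **agg_kw)
        station_table = station_seasonal_table(pm_sites, window="JJA", **agg_kw)
        eligible = site_eligibility(station_table, min_years=config.min_years_site,
                                    years=(config.year_start, config.year_end))
        station_table.to_csv(outdir / "station_seasonal_jja_pm25.csv", index=False)
        report.add(stage, len(pm_sites), len(pm_sites) - len(eligible),
                   {"eligible_pm25_sites": len(eligible)})
        if finished("aggregate"):
            (outdir / "report.json").write_text(report.to_json())
            return report

        # ---- estimate -------------------------------------------------
        stage = "estimate"
        maps = {}
        for var, window in WINDOWS:
            smap = gridwise_sensitivity(seasonal[(var, window)], temp_jja, alpha=config.alpha)
            smap.attrs["period"] = [config.year_start, config.year_end]
            maps[(var, window)] = smap
            write_grid(smap, outdir / f"sensitivity_{var}_{window}.nc")
        # per-site estimates from the co-located station networks
        site_rows = []
        eligible_records = [r for r in pm_sites if r.site_id in eligible]
        pairs_by_site = colocate_station_pairs(eligible_records, temp_sites,
                                               radius_km=config.colocate_radius_km)
        for pair in pairs_by_site:
            sy = station_table[(station_table.site_id == pair.site.site_id)
                               & station_table.complete].set_index("year")["value"]
            t_tab = station_seasonal_table([StationRecord(
                pair.site.site_id, pair.site.latitude, pair.site.longitude,
                "temperature", "degC", pair.temperature)], window="JJA", **agg_kw)
            tt = t_tab[t_tab.complete].set_index("year")["value"]
            common = sy.index.intersection(tt.index)
            if len(common) < 3:
                continue
            est = sensitivity_slope(
                detrend(common.to_numpy(), tt.loc[common].to_numpy(),
                        unit_id=pair.site.site_id),
                detrend(common.to_numpy(), sy.loc[common].to_numpy(),
                        unit_id=pair.site.site_id),
                alpha=config.alpha,
            )
            site_rows.append({
                "site_id": pair.site.site_id, "lat": pair.site.latitude,
                "lon": pair.site.longitude, "window": "JJA", "slope": est.slope,
                "se": est.se, "p": est.p_value, "n": est.n_years,
            })
        pd.DataFrame(site_rows).to_csv(outdir / "station_sensitivity_jja_pm25.csv",
                                       index=False)
        n_est = sum(int(np.isfinite(m["slope"].values).sum()) for m in maps.values())
        report.add(stage, n_cells * len(maps), n_cells * len(maps) - n_est,
                   {"station_estimates": len(site_rows)})
        if finished("estimate"):
            (outdir / "report.json").write_text(report.to_json())
            return report

        # ---- regional -------------------------------------------------
        stage = "regional"
        rows = []
        change_rows = []
        periods = {
            "full": (config.year_start, config.year_end),
            "early": config.period_early,
            "late": config.period_late,
        }
        for var, window in WINDOWS:
            per_period = {}
            for pname, period in periods.items():
                anoms = period_anomalies(seasonal[(var, window)], temp_jja, period=period)
                for code, rname in REGION_CODES.items():
                    pairs = pool_region_anomalies(anoms, mask, region=code)
                    est = bootstrap_regional(pairs, b=config.bootstrap_b,
                                             seed=config.seed, ci_method=config.bootstrap_ci)
                    est.region = rname
                    per_period.setdefault(pname, {})[rname] = est
                    rows.append({
                        "variable": var, "window": window, "region": rname,
                        "period": f"{period[0]}-{period[1]}", "slope": est.slope,
                        "se": est.se, "ci_lo": est.ci[0], "ci_hi": est.ci[1],
                        "n": est.n_points, "B": est.b, "seed": est.seed,
                    })
            for rname in REGION_CODES.values():
                ch = period_change(per_period["early"][rname], per_period["late"][rname])
                change_rows.append({
                    "variable": var, "window": window, "region": rname,
                    "slope_early": ch.slope_early, "slope_late": ch.slope_late,
                    "percent_change": ch.percent_change,
                    "ci_lo": ch.ci[0] if ch.ci else "",
                    "ci_hi": ch.ci[1] if ch.ci else "",
                    "significant": ch.significant, "undefined": ch.undefined,
                })
            mw = moving_window_sensitivity(seasonal[(var, window)], temp_jja)
            pd.DataFrame([
                {"variable": var, "window": window,
                 "start": est.period[0], "end": est.period[1],
                 "slope": est.slope, "se": est.se, "n": est.n_points}
                for est in mw
            ]).to_csv(outdir / f"moving_window_{var}_{window}.csv", index=False)
        pd.DataFrame(rows).to_csv(outdir / "regional_sensitivity.csv", index=False)
        pd.DataFrame(change_rows).to_csv(outdir / "period_change.csv", index=False)
        report.add(stage, len(rows), 0, {"n_period_changes": len(change_rows)})
        if finished("regional"):
            (outdir / "report.json").write_text(report.to_json())
            return report

        # ---- exposure -------------------------------------------------
        stage = "exposure"
        weights = align_population(pop, maps[("pm25", "JJA")])
        urb = urban_mask(pop, cutoff=config.urban_cutoff)
        exp_rows = []
        for var, window in WINDOWS:
            full_map = prepare_exposure_map(maps[(var, window)])
            thr = derive_threshold(full_map, weights, tail=config.threshold_tail,
                                   override=config.threshold_overrides.get(f"{var}_{window}"))
            for pname in ("early", "late"):
                p0, p1 = periods[pname]
                yrs = seasonal[(var, window)]["year"].values
                sel = (yrs >= p0) & (yrs <= p1)
                pmap = gridwise_sensitivity(
                    seasonal[(var, window)].isel(year=sel),
                    temp_jja.isel(year=sel),
                    alpha=config.alpha,
                )
                pmap.attrs["window"] = window
                pmap = prepare_exposure_map(pmap)
                dist = exposure_distribution(pmap, weights, thr,
                                             probs=config.exposure_probs,
                                             period=periods[pname])
                exp_rows.append({
                    "variable": var, "window": window,
                    "period": f"{periods[pname][0]}-{periods[pname][1]}",
                    "weighting": "population",
                    **{f"q{int(100 * p):02d}": q for p, q in zip(dist.probs, dist.quantiles)},
                    "threshold": thr, "fraction_above": dist.fraction_above,
                    "total_weight": dist.total_weight,
                })
        anoms_o3 = period_anomalies(seasonal[("o3", "JJA")], temp_jja)
        strat_u, strat_n = stratified_sensitivity(anoms_o3, urb)
        write_grid(urb.astype("int8").to_dataset(name="urban"), outdir / "urban_mask.nc")
        pd.DataFrame(exp_rows).to_csv(outdir / "exposure.csv", index=False)
        pd.DataFrame([
            {"stratum": "urban",
             "slope": strat_u.slope if strat_u else "", "n": strat_u.n_points if strat_u else 0},
            {"stratum": "nonurban",
             "slope": strat_n.slope if strat_n else "", "n": strat_n.n_points if strat_n else 0},
        ]).to_csv(outdir / "urban_stratification.csv", index=False)
        report.add(stage, len(exp_rows), 0,
                   {"urban_cells": int(urb.values.sum())})
        if finished("exposure"):
            (outdir / "report.json").write_text(report.to_json())
            return report

        # ---- species --------------------------------------------------
        stage = "species"
        species_records = {}
        for s in ("sulfate", "nitrate", "ammonium", "oc", "ec"):
            species_records[s] = sample_stations(
                fields[s], config.n_sites, config.sampling_interval_days,
                config.miss_rate, seed=config.seed + 10,
            )
        spec = component_sensitivity(
            species_records, temp_sites, region_mask=None,
            min_days=config.min_days_month,
            min_months_summer=config.min_months_summer,
            min_months_annual=config.min_months_annual,
            min_years=config.min_years_site,
            study_years=(config.year_start, config.year_end),
            radius_km=config.colocate_radius_km,
        )
        frac = contribution_fractions(spec) if spec else {}
        pd.DataFrame([
            {"species": s.species, "region": s.region, "window": s.window,
             "slope": s.slope, "se": s.se, "p": s.p_value, "n": s.n,
             "fraction": frac.get(s.species, {}).get("fraction", ""),
             "excluded": frac.get(s.species, {}).get("excluded", "")}
            for s in spec
        ]).to_csv(outdir / "species_sensitivity.csv", index=False)
        report.add(stage, len(species_records), len(species_records) - len(spec))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "report.json").write_text(report.to_json())
    return report
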