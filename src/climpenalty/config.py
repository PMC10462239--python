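"""Run configuration: defaults, validation, and the flat key-value format."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "validate_config", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Defaults encode the study conditions: JJA summer, months complete
    with >= 7 daily values, summers with >= 2 months, June–May years
    with >= 9 months, sites with >= 11 seasonal values, alpha 0.05,
    B = 1000 bootstrap replicates, early/late periods 2000–2009 and
    2010–2016, exposure quantiles 5/25/50/75/95%, urban cutoff
    400 people/km2.
    """

    scenario: str = "two-region"
    seed: int = 0
    n_lat: int = 20
    n_lon: int = 30
    year_start: int = 2000
    year_end: int = 2016
    summer_months: tuple[int, ...] = (6, 7, 8)
    min_days_month: int = 7
    min_months_summer: int = 2
    min_months_annual: int = 9
    min_years_site: int = 11
    alpha: float = 0.05
    bootstrap_b: int = 1000
    bootstrap_ci: str = "expanded"
    period_early: tuple[int, int] = (2000, 2009)
    period_late: tuple[int, int] = (2010, 2016)
    exposure_probs: tuple[float, ...] = (0.05, 0.25, 0.50, 0.75, 0.95)
    threshold_tail: float = 0.25
    threshold_overrides: dict = field(default_factory=dict)  # window -> units/degC
    urban_cutoff: float = 400.0
    n_sites: int = 40
    n_temp_stations: int = 60
    sampling_interval_days: int = 3
    miss_rate: float = 0.1
    colocate_radius_km: float = 30.0
    grid_colocate_radius_km: float = 5.0
    n_pop_clusters: int = 5
    outdir: str = "climpenalty_out"

    def validate(self) -> "RunConfig":
        errors = []
        if self.year_end - self.year_start < 2:
            errors.append("year range must span at least 3 years")
        for key in ("min_days_month", "min_months_summer", "min_months_annual",
                    "min_years_site", "bootstrap_b", "n_sites", "n_temp_stations",
                    "sampling_interval_days", "n_pop_clusters"):
            if getattr(self, key) < 1:
                errors.append(f"{key} must be >= 1")
        if not (0 < self.alpha < 1):
            errors.append("alpha must be in (0, 1)")
        if not (0 <= self.miss_rate < 1):
            errors.append("miss_rate must be in [0, 1)")
        if not (0 < self.threshold_tail < 1):
            errors.append("threshold_tail must be in (0, 1)")
        if self.urban_cutoff <= 0:
            errors.append("urban_cutoff must be positive")
        for key in ("colocate_radius_km", "grid_colocate_radius_km"):
            if getattr(self, key) <= 0:
                errors.append(f"{key} must be positive")
        for name, (a, b) in (("period_early", self.period_early), ("period_late", self.period_late)):
            if a > b:
                errors.append(f"{name}: start year after end year")
            if a < self.year_start or b > self.year_end:
                errors.append(f"{name} {a}-{b} outside the data span "
                              f"{self.year_start}-{self.year_end}")
        e, l = self.period_early, self.period_late
        if not (e[1] < l[0] or l[1] < e[0]):
            errors.append("period_early and period_late overlap")
        for t in self.threshold_overrides.values():
            if t is not None and t <= 0:
                errors.append("exposure thresholds must be positive")
        if any(not (0 < p < 1) for p in self.exposure_probs):
            errors.append("exposure_probs must lie in (0, 1)")
        if self.bootstrap_ci not in ("expanded", "percentile", "basic", "normal"):
            errors.append(f"unknown bootstrap_ci {self.bootstrap_ci!r}")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        return self


_TUPLE_KEYS = {"summer_months", "period_early", "period_late", "exposure_probs"}


def validate_config(raw: Mapping[str, Any] | None) -> RunConfig:
    """Build a RunConfig from a raw key-value document.

    Missing keys take defaults; unknown keys are rejected with their
    paths; type and range violations raise with the offending key.
    """
    raw = dict(raw or {})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    coerced: dict[str, Any] = {}
    for key, val in raw.items():
        if key in _TUPLE_KEYS:
            if not isinstance(val, (list, tuple)):
                raise ValueError(f"{key}: expected a list, got {type(val).__name__}")
            coerced[key] = tuple(val)
        else:
            coerced[key] = val
    return RunConfig(**coerced).validate()


def load_config(path) -> RunConfig:
    """Read a flat YAML/key-value config file and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value document")
    return validate_config(raw)
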