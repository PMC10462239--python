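# Methods

## The model

The quantity this package estimates is the *climate penalty* on air
quality: the change in a surface pollutant's seasonal-mean
concentration per 1 °C of interannual summer-temperature anomaly,
after long-term means and linear trends have been removed from both
sides. For a site or grid cell with seasonal means `y_t` (pollutant)
and summer-mean temperature `T_t` over years `t`, the statistic is

    m(Δy) = slope of OLS fit of Δy_t on ΔT_t,

where `Δy_t` and `ΔT_t` are the residuals of separate OLS fits of
`y_t` and `T_t` on the year index. Detrending by one OLS-on-year pass
removes the mean and the linear trend simultaneously; by the
Frisch–Waugh–Lovell theorem, `m(Δy)` is identical to the temperature
coefficient of the joint regression of raw `y_t` on `(T_t, t)`, which
the test suite verifies to 1e-9 relative. The linear trend stands in
for emission-driven concentration decline, so the slope isolates
meteorologically driven variability.

Three windows are analysed: summer PM2.5 (JJA mean, μg/m³/°C), annual
PM2.5 over the twelve months from June through the following May
(μg/m³/°C), and summer 8-h-maximum O3 (ppb/°C). The temperature
regressor is always the JJA mean of `(tmax + tmin)/2`.

## Aggregation and completeness filters

Daily records become monthly means only when a month has at least 7
daily values ("more than 6"); summers need at least 2 of their 3
monthly means; June–May years need at least 9 of 12 ("more than
eight"); and a site enters the analysis only with at least 11 complete
seasonal values inside the study years. Months are weighted equally in
seasonal means (monthly-then-seasonal construction, not day-count
weighting). Incomplete windows are dropped, never imputed. All
thresholds are configurable; grid cells pass through the same filters
as stations so grid/station comparisons are like-for-like (on complete
synthetic grids the filters are vacuous).

The summer window is JJA by default. The month set is exposed as
configuration (`summer_months` / the `months` argument) for analyses
that prefer a July–September window; nothing else changes.

## Regional pooling and the bootstrap

A regional sensitivity pools *all* detrended cell-year (or site-year)
anomaly pairs in the region into one unweighted OLS fit. Uncertainty
comes from a block bootstrap over **years**: a replicate resamples the
set of years with replacement and keeps every cell of a resampled year
together, because the anomaly fields are strongly spatially correlated
within a year — resampling cells would fabricate independence. The
default is B = 1000 replicates.

With only ~17 annual blocks, the plain percentile interval is
systematically short (measured at roughly 89% coverage for a nominal
95% interval in this package's calibration runs), so the default
interval is the *expanded percentile*: percentile levels adjusted by
the small-sample t correction `Φ(−t_{n−1,α/2}·√(n/(n−1)))` with `n`
the number of distinct years. This restores ~93% measured coverage at
study conditions. `percentile`, `basic`, and `normal` intervals remain
available via `bootstrap_ci`.

Period-contrast estimates (2000–2009 vs 2010–2016) re-detrend within
each period, so the removed trend matches the data actually fit;
full-record detrending is available by passing `period=None` when
building anomalies. The percentage change between periods is
`100·(m_late − m_early)/m_early`, defined only for a positive early
slope; a nonpositive early slope is reported as an undefined
"no penalty → penalty" transition rather than a percentage. Its
confidence interval pairs bootstrap draw *i* of the early period with
draw *i* of the late one. Moving-window trends use 5-year windows
starting at every year (thirteen windows for a 17-year record), with
within-window detrending.

## Exposure analysis

Sensitivity maps entering exposure analysis have negative slopes
clamped to zero (negative sensitivities are overwhelmingly
insignificant and are treated as "no penalty"); the raw signed maps
are preserved for mapping. Population counts are assigned to
sensitivity cells by nearest grid center, conserving the total count
exactly. Weighted quantiles use the left-continuous inverse CDF —
the smallest value whose cumulative normalised weight reaches `p` —
which is deterministic and directly checkable against exhaustive
enumeration. The high-penalty threshold is the population-weighted
75th percentile of the full-record clamped map (computed on the
clamped map; overrides such as 1 μg/m³/°C, 0.5 μg/m³/°C, and 3 ppb/°C
can be supplied as configuration). Exceedance fractions use
`slope ≥ threshold`. Cell areas are `(cell_deg·111.32 km)²·cos(lat)`,
adequate for the fraction ratios computed here. Urban cells are those
with population density ≥ 400 people/km².

## Species attribution

Per-component sensitivities (sulfate, nitrate, ammonium, OA, EC) run
through exactly the same filters, 30-km datewise temperature
co-location, detrending, and pooling as total PM2.5; organic carbon is
converted to organic aerosol mass with a factor 2.1 before analysis.
Contribution fractions are `max(m_s, 0)/Σ max(m_s, 0)`; species with
nonpositive slopes contribute zero and are flagged excluded. On
synthetic data whose species fields exactly partition PM2.5 and share
the temperature draws, species slopes (plus the residual's) sum to the
total slope to 1e-9; with real networks the species and total
estimates come from different sites, times, and counts, and this
identity is not expected to hold. Multiple in-radius temperature
stations are averaged datewise *before* monthly aggregation; this
order is a package choice and is configurable in principle by
pre-merging station lists.

## The synthetic domain

The generator inverts the analysis model so that ground truth is known
exactly. Daily pollutant concentration at cell `c` in "pollution year"
`y` (June of `y` through May of `y+1`) is

    baseline(c) + trend(c)·(y − y0) + β(c)·ΔT(c, y) + ε(c, d),

with `ΔT` a zero-mean spatially correlated anomaly drawn once per
year (white noise smoothed by a Gaussian kernel of width
`spatial_corr_len` cells and standardised per draw — the covariance
form is a generator choice, exposed as configuration) and `ε` iid
daily noise. Temperature is a fixed sinusoidal seasonal cycle plus the
same `ΔT`, split into `tmax = tmean + 5` and `tmin = tmean − 5`. The
seasonal cycle is keyed to (month, day) on a 365-day calendar so leap
years do not perturb summer means, and the daily axis runs 1 June of
the first year through 31 May after the last so every JJA and June–May
window is complete. Species fields split the deterministic part by
mass shares with their own betas; the `residual` field closes the sum
to the total exactly.

Default study conditions: a 20×30 grid of 0.25° cells, years
2000–2016, PM2.5 baseline 10 μg/m³ with trend −0.15 μg/m³/yr and O3
baseline 45 ppb with trend −0.25 ppb/yr (declines of roughly the
reported 24% and 9% over the period), interannual summer-temperature
anomaly SD 0.8 °C (typical mid-latitude JJA variability), spatial
correlation length 3 cells, and daily noise calibrated so the
JJA-mean noise SD is 0.5 concentration units
(`daily_sd_for_seasonal_sd`). Station networks sample distinct cell
centers every 3 days (the 24-h filter-sample cadence) with independent
dropout. Population is a log-normal-peak cluster field over a sparse
rural background, constructed to straddle the 400 people/km² urban
cutoff. All randomness flows from one seed through named
deterministic sub-streams, so outputs are bit-identical per seed.

What the generator does *not* emulate: the error structure of the
machine-learning concentration fields (noise here is iid by design),
wildfire events (decadal beta shifts stand in for changing fire
regimes), humidity/precipitation/wind covariates, and orography.
Passing tests therefore demonstrate the statistical machinery is
correct under the stated model, not that real fields satisfy that
model.

## Numerical choices and degenerate inputs

Detrending needs ≥ 3 distinct years; cells or sites below that are
missing, not errors, in map outputs. A temperature anomaly series with
zero variance yields a flagged degenerate estimate (NaN slope).
Listwise deletion aligns pollutant and temperature years; no
imputation anywhere. Cell-level p-values are two-sided t tests at
n − 2 degrees of freedom with α = 0.05 and no multiple-testing
correction. Bootstrap replicates with numerically zero temperature
variance are skipped (more than 10% skipped is an error). Great-circle
distances use a 6371-km sphere. Weighted-quantile ties resolve to the
first value reaching the cumulative weight, making
`prepare_exposure_map` → threshold → exceedance fully deterministic.

## Problem sizes used in checks

The shipped checks run at desk scale, chosen so the whole suite
completes in a few minutes: cellwise recovery on 200 simulated 20×30
domains, decadal-change recovery on 100 domains with B = 1000,
bootstrap calibration on 500 repeats of an 8×8 domain, and oracle
comparisons on 1000 (detrending) and 200 (joint-regression) random
instances. The estimator is resolution-agnostic; the 0.25° grid stands
in for the 1-km national fields the method is designed for, whose
headline regional values are not reproducible at this scale.

## Known limitations

- The spatial covariance of the anomaly fields is a kernel-smoothing
  stand-in; real fields have richer (anisotropic, nonstationary)
  structure.
- The year-block bootstrap addresses cross-cell dependence within a
  year but not multi-year autocorrelation.
- Negative-slope clamping before thresholding is a convention; the
  package exposes the signed maps for anyone preferring the other
  choice.
- Pooled regional fits are unweighted across cells; an area-weighted
  variant can be composed from `cell_areas_km2` but is not the
  default.
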