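"""Detrending, slope estimation, co-location geometry, and clamping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import climpenalty as cp
from climpenalty.estimation import haversine_km


class TestDetrend:
    def test_constant_series_gives_zero_anomalies(self):
        a = cp.detrend([2000, 2001, 2002], [5.0, 5.0, 5.0])
        np.testing.assert_allclose(a.values, 0.0, atol=1e-12)

    def test_pure_trend_gives_zero_anomalies(self):
        years = np.arange(2000, 2010)
        a = cp.detrend(years, 3.0 + 2.0 * (years - 2000))
        np.testing.assert_allclose(a.values, 0.0, atol=1e-9)

    def test_closed_form_oracle_five_points(self):
        # years 2000-2004, values (1,3,2,5,4): OLS slope 0.8, intercept 1.4 at 2000
        a = cp.detrend(np.arange(2000, 2005), [1.0, 3.0, 2.0, 5.0, 4.0])
        np.testing.assert_allclose(a.values, [-0.4, 0.8, -1.0, 1.2, -0.6], atol=1e-12)

    def test_rejects_short_or_degenerate(self):
        with pytest.raises(ValueError):
            cp.detrend([2000, 2001], [1.0, 2.0])
        with pytest.raises(ValueError):
            cp.detrend([2000, 2000, 2000], [1.0, 2.0, 3.0])

    def test_missing_values_dropped(self):
        a = cp.detrend(np.arange(2000, 2006), [1.0, np.nan, 2.0, 5.0, np.nan, 4.0])
        assert a.n_years == 4

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(4, 20),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_anomalies_mean_zero_and_trend_orthogonal(self, n, seed):
        rng = np.random.default_rng(seed)
        years = 2000 + np.sort(rng.choice(50, n, replace=False))
        vals = rng.normal(10, 5, n)
        a = cp.detrend(years, vals)
        scale = max(np.abs(vals).max(), 1.0)
        assert abs(a.values.mean()) < 1e-9 * scale
        assert abs(np.dot(a.values, years - years.mean())) < 1e-9 * scale * n * 50


class TestSensitivitySlope:
    def _anom(self, years, values, uid="u"):
        return cp.AnomalySeries(uid, np.asarray(years), np.asarray(values, float))

    def test_null_response_slope_zero(self):
        t = self._anom([0, 1, 2], [-1.0, 0.0, 1.0])
        y = self._anom([0, 1, 2], [0.0, 0.0, 0.0])
        assert cp.sensitivity_slope(t, y).slope == pytest.approx(0.0)

    def test_exact_proportionality(self):
        t = self._anom([0, 1, 2], [-1.0, 0.0, 1.0])
        y = self._anom([0, 1, 2], [-2.0, 0.0, 2.0])
        est = cp.sensitivity_slope(t, y)
        assert est.slope == pytest.approx(2.0) and est.r == pytest.approx(1.0)

    def test_hand_ols_oracle(self):
        # Sxy = 5, Sxx = 5 -> slope 1.0
        t = self._anom([0, 1, 2, 3], [-1.5, -0.5, 0.5, 1.5])
        y = self._anom([0, 1, 2, 3], [-2.0, 1.0, -1.0, 2.0])
        assert cp.sensitivity_slope(t, y).slope == pytest.approx(1.0)

    def test_degenerate_temperature_flagged(self):
        t = self._anom([0, 1, 2], [0.0, 0.0, 0.0])
        y = self._anom([0, 1, 2], [1.0, 2.0, 3.0])
        est = cp.sensitivity_slope(t, y)
        assert est.degenerate and np.isnan(est.slope)

    def test_listwise_deletion_on_disjoint_years(self):
        t = self._anom([0, 1, 2, 3], [-1.0, 0.0, 1.0, 2.0])
        y = self._anom([1, 2, 3, 4], [0.0, 1.0, 2.0, 5.0])
        est = cp.sensitivity_slope(t, y)
        assert est.n_years == 3

    def test_significance_flag_matches_alpha(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=17)
        t = self._anom(range(17), x)
        y = self._anom(range(17), 3 * x + rng.normal(0, 0.1, 17))
        est = cp.sensitivity_slope(t, y, alpha=0.05)
        assert est.significant and est.p_value < 1e-6


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(5, 25))
def test_fwl_equivalence_detrended_slope_equals_joint_regression(seed, n):
    """The detrend-then-regress slope equals the temperature coefficient
    of the joint OLS of raw pollutant on (temperature, year)."""
    rng = np.random.default_rng(seed)
    years = np.arange(2000, 2000 + n)
    t = 15 + rng.normal(0, 1, n)
    y = 10 - 0.3 * (years - 2000) + 1.7 * t + rng.normal(0, 1, n)
    at = cp.detrend(years, t)
    ay = cp.detrend(years, y)
    slope = cp.sensitivity_slope(at, ay).slope
    X = np.column_stack([np.ones(n), t, years.astype(float)])
    joint = np.linalg.lstsq(X, y, rcond=None)[0][1]
    assert slope == pytest.approx(joint, rel=1e-9, abs=1e-12)


class TestGridwise:
    def test_flat_truth_recovered_exactly(self, flat_truth, flat_seasonal):
        m = cp.gridwise_sensitivity(flat_seasonal["pm_jja"], flat_seasonal["t_jja"])
        np.testing.assert_allclose(m["slope"].values, flat_truth.beta_pm, atol=1e-9)

    def test_two_region_truth_recovered(self):
        truth = cp.make_truth(seed=9, shape=(6, 8), years=(2000, 2008),
                              scenario="two-region", noise_seasonal_sd=0.0)
        f = cp.simulate_fields(truth, variables=("temperature", "pm25"))
        tmean = (f["tmax"] + f["tmin"]) / 2.0
        m = cp.gridwise_sensitivity(cp.grid_seasonal_means(f["pm25"], "JJA"),
                                    cp.grid_seasonal_means(tmean, "JJA"))
        np.testing.assert_allclose(m["slope"].values, truth.beta_pm, atol=1e-9)
        assert truth.beta_pm.min() == 0.5 and truth.beta_pm.max() == 2.0

    def test_cell_with_two_years_missing(self, flat_seasonal):
        pm = flat_seasonal["pm_jja"].copy(deep=True)
        pm["value"].values[:-2, 0, 0] = np.nan  # leave 2 years only
        m = cp.gridwise_sensitivity(pm, flat_seasonal["t_jja"])
        assert np.isnan(m["slope"].values[0, 0])
        assert np.isfinite(m["slope"].values[1, 1])

    def test_grid_mismatch_rejected(self, flat_seasonal):
        shifted = flat_seasonal["t_jja"].assign_coords(lat=flat_seasonal["t_jja"].lat + 1)
        with pytest.raises(ValueError, match="aligned"):
            cp.gridwise_sensitivity(flat_seasonal["pm_jja"], shifted)


class TestColocation:
    def _station(self, sid, lat, lon, values, var="temperature"):
        idx = pd.date_range("2000-01-01", periods=len(values), freq="D")
        return cp.StationRecord(sid, lat, lon, var, "degC", pd.Series(values, index=idx))

    def test_identical_coordinates_paired(self):
        p = self._station("P", 40.0, -100.0, [1.0, 2.0], var="pm25")
        t = self._station("T", 40.0, -100.0, [10.0, 12.0])
        pairs = cp.colocate_station_pairs([p], [t], radius_km=30)
        assert len(pairs) == 1 and pairs[0].n_temp_stations == 1

    def test_haversine_oracle_25p6_km(self):
        d = haversine_km(40.0, -100.0, 40.0, -99.7)
        assert d == pytest.approx(25.6, abs=0.1)
        p = self._station("P", 40.0, -100.0, [1.0], var="pm25")
        t = self._station("T", 40.0, -99.7, [10.0])
        assert len(cp.colocate_station_pairs([p], [t], radius_km=30)) == 1
        assert len(cp.colocate_station_pairs([p], [t], radius_km=20)) == 0

    def test_in_radius_stations_averaged_datewise(self):
        p = self._station("P", 40.0, -100.0, [1.0], var="pm25")
        t1 = self._station("T1", 40.01, -100.0, [10.0])
        t2 = self._station("T2", 39.99, -100.0, [20.0])
        pairs = cp.colocate_station_pairs([p], [t1, t2])
        assert pairs[0].temperature.iloc[0] == pytest.approx(15.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_distance_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform([25, -120], [49, -70], size=(3, 2))
        d = lambda a, b: float(haversine_km(a[0], a[1], b[0], b[1]))  # noqa: E731
        a, b, c = pts
        assert d(a, b) == pytest.approx(d(b, a), rel=1e-12)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-9


class TestExtractColocatedGrid:
    def test_site_at_cell_center_gets_that_cell(self, flat_fields):
        da = flat_fields["pm25"]
        lat, lon = float(da.lat[1]), float(da.lon[2])
        site = cp.StationRecord("S", lat, lon, "pm25", "ug/m3",
                                pd.Series([1.0], index=pd.DatetimeIndex(["2000-06-01"])))
        series = cp.extract_colocated_grid(da, [site], radius_km=5)["S"]
        np.testing.assert_array_equal(series.to_numpy(), da.values[:, 1, 2])

    def test_site_between_cells_with_tiny_radius_dropped(self, flat_fields):
        da = flat_fields["pm25"]
        lat = float(da.lat[1]) + 0.125  # halfway between 0.25-degree centers
        site = cp.StationRecord("S", lat, float(da.lon[2]), "pm25", "ug/m3",
                                pd.Series([1.0], index=pd.DatetimeIndex(["2000-06-01"])))
        with pytest.warns(UserWarning, match="dropped"):
            out = cp.extract_colocated_grid(da, [site], radius_km=5)
        assert out == {}

    def test_equidistant_cells_averaged(self, flat_fields):
        da = flat_fields["pm25"]
        lat = 0.5 * (float(da.lat[1]) + float(da.lat[2]))
        site = cp.StationRecord("S", lat, float(da.lon[2]), "pm25", "ug/m3",
                                pd.Series([1.0], index=pd.DatetimeIndex(["2000-06-01"])))
        series = cp.extract_colocated_grid(da, [site], radius_km=16)["S"]
        expected = 0.5 * (da.values[:, 1, 2] + da.values[:, 2, 2])
        np.testing.assert_allclose(series.to_numpy(), expected)


class TestPrepareExposureMap:
    def _map(self, slopes):
        import xarray as xr
        slopes = np.asarray(slopes, float)
        return xr.Dataset(
            {"slope": (("lat", "lon"), slopes),
             "p_value": (("lat", "lon"), np.full_like(slopes, 0.01))},
            coords={"lat": np.arange(slopes.shape[0]), "lon": np.arange(slopes.shape[1])},
        )

    def test_negatives_clamped_nonnegatives_kept(self):
        m = cp.prepare_exposure_map(self._map([[-0.3, 1.2], [0.0, -5.0]]))
        np.testing.assert_array_equal(m["slope"].values, [[0.0, 1.2], [0.0, 0.0]])
        assert float(m["p_value"].min()) == 0.01

    def test_idempotent(self):
        m0 = self._map([[-1.0, 2.0], [0.5, -0.1]])
        m1 = cp.prepare_exposure_map(m0)
        m2 = cp.prepare_exposure_map(m1)
        np.testing.assert_array_equal(m1["slope"].values, m2["slope"].values)

    def test_nan_preserved(self):
        m = cp.prepare_exposure_map(self._map([[np.nan, -1.0], [1.0, 0.0]]))
        assert np.isnan(m["slope"].values[0, 0])
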