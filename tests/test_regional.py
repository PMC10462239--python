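"""Regional pooling, year-block bootstrap, decadal change, moving windows."""

import numpy as np
import pytest
import xarray as xr

import climpenalty as cp
from climpenalty.regional import PooledPairs, RegionalSensitivity, bootstrap_ci


def _pairs(t, y, years=None, region="all"):
    t = np.asarray(t, float)
    years = np.asarray(years if years is not None else np.arange(len(t)), int)
    return PooledPairs(region=region, window="JJA", period=(int(years.min()), int(years.max())),
                       year_labels=years, t=t, y=np.asarray(y, float))


@pytest.fixture(scope="module")
def flat_anoms(flat_seasonal):
    return cp.period_anomalies(flat_seasonal["pm_jja"], flat_seasonal["t_jja"])


class TestPooling:
    def test_pair_count_two_cells_three_years(self):
        ds = xr.Dataset(
            {"dt": (("year", "lat", "lon"), np.random.default_rng(0).normal(size=(3, 1, 2))),
             "dy": (("year", "lat", "lon"), np.random.default_rng(1).normal(size=(3, 1, 2)))},
            coords={"year": [2000, 2001, 2002], "lat": [0.0], "lon": [0.0, 1.0]},
        )
        pairs = cp.pool_region_anomalies(ds, None)
        assert pairs.n_points == 6

    def test_period_filter_restricts_years(self, flat_seasonal):
        anoms = cp.period_anomalies(flat_seasonal["pm_jja"], flat_seasonal["t_jja"],
                                    period=(2000, 2004))
        pairs = cp.pool_region_anomalies(anoms, None)
        assert set(pairs.years) == set(range(2000, 2005))

    def test_count_matches_brute_force_on_masked_grid(self, flat_anoms, flat_truth):
        mask = cp.make_region_mask(flat_truth)
        total = 0
        for code in (1, 2, 3, 4):
            pairs = cp.pool_region_anomalies(flat_anoms, mask, region=code)
            expected = int((mask.values == code).sum()) * len(flat_anoms.year)
            assert pairs.n_points == expected
            total += pairs.n_points
        assert total == mask.size * len(flat_anoms.year)

    def test_empty_region_rejected(self, flat_anoms, flat_truth):
        mask = cp.make_region_mask(flat_truth)
        with pytest.raises(ValueError, match="no cells"):
            cp.pool_region_anomalies(flat_anoms, mask, region=99)

    def test_pooling_order_invariant(self, flat_anoms):
        pairs = cp.pool_region_anomalies(flat_anoms, None)
        rng = np.random.default_rng(3)
        perm = rng.permutation(pairs.n_points)
        shuffled = PooledPairs(pairs.region, pairs.window, pairs.period,
                               pairs.year_labels[perm], pairs.t[perm], pairs.y[perm])
        a = cp.regional_sensitivity(pairs)
        b = cp.regional_sensitivity(shuffled)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)


class TestRegionalSlope:
    def test_three_point_oracle(self):
        est = cp.regional_sensitivity(_pairs([-1, 0, 1], [-2, 0, 2]))
        assert est.slope == pytest.approx(2.0)

    def test_replication_invariance(self):
        t = np.array([-1.0, 0.0, 1.0, 0.5])
        y = 1.3 * t + np.array([0.1, -0.2, 0.1, 0.0])
        single = cp.regional_sensitivity(_pairs(t, y))
        rep = cp.regional_sensitivity(_pairs(np.tile(t, 5), np.tile(y, 5),
                                             years=np.tile(np.arange(4), 5)))
        assert rep.slope == pytest.approx(single.slope, rel=1e-12)

    def test_equal_leverage_average_of_two_betas(self):
        # two cells share the same dT draws, betas 1 and 3, zero noise -> pooled slope 2
        rng = np.random.default_rng(5)
        dt = rng.normal(0, 1, 9)
        dt -= dt.mean()
        t = np.concatenate([dt, dt])
        y = np.concatenate([1.0 * dt, 3.0 * dt])
        est = cp.regional_sensitivity(_pairs(t, y, years=np.tile(np.arange(9), 2)))
        assert est.slope == pytest.approx(2.0, rel=1e-10)

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cp.regional_sensitivity(_pairs([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]))


class TestBootstrap:
    def test_zero_noise_constant_beta_ci_width_zero(self, flat_anoms):
        pairs = cp.pool_region_anomalies(flat_anoms, None)
        est = cp.bootstrap_regional(pairs, b=200, seed=1)
        assert est.slope == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(est.draws, est.slope, atol=1e-9)
        assert est.ci[1] - est.ci[0] == pytest.approx(0.0, abs=1e-9)

    def test_b_zero_rejected(self, flat_anoms):
        pairs = cp.pool_region_anomalies(flat_anoms, None)
        with pytest.raises(ValueError):
            cp.bootstrap_regional(pairs, b=0)

    def test_deterministic_for_fixed_seed(self, flat_anoms):
        pairs = cp.pool_region_anomalies(flat_anoms, None)
        a = cp.bootstrap_regional(pairs, b=50, seed=42)
        b = cp.bootstrap_regional(pairs, b=50, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_bootstrap_se_comparable_to_ols_se(self):
        """On homoscedastic data the bootstrap spread tracks the OLS standard error."""
        rng = np.random.default_rng(7)
        ny, j = 17, 20
        x = np.repeat(rng.normal(0, 0.8, ny), j)
        y = 1.5 * x + rng.normal(0, 0.5, ny * j)
        pairs = _pairs(x, y, years=np.repeat(np.arange(ny), j))
        est = cp.bootstrap_regional(pairs, b=1000, seed=7)
        ratio = est.draws.std(ddof=1) / est.se
        assert 1 / 1.5 < ratio < 1.5

    def test_ci_methods_all_bracket_point_on_symmetric_data(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 60)
        y = 2.0 * x + rng.normal(0, 0.3, 60)
        pairs = _pairs(x, y, years=np.repeat(np.arange(12), 5))
        for method in ("expanded", "percentile", "basic", "normal"):
            est = cp.bootstrap_regional(pairs, b=500, seed=2, ci_method=method)
            assert est.ci[0] < est.slope < est.ci[1]

    def test_expanded_interval_wider_than_percentile(self):
        draws = np.random.default_rng(0).normal(size=2000)
        lo_p, hi_p = bootstrap_ci(draws, 0.0, n_blocks=17, method="percentile")
        lo_e, hi_e = bootstrap_ci(draws, 0.0, n_blocks=17, method="expanded")
        assert lo_e < lo_p and hi_e > hi_p


class TestPeriodChange:
    def _est(self, slope, draws=None, region="SE"):
        return RegionalSensitivity(region=region, window="JJA", period=(0, 0),
                                   slope=slope, se=0.1, n_points=100, n_years=10,
                                   draws=None if draws is None else np.asarray(draws, float),
                                   ci_method="expanded")

    def test_printed_ozone_slopes_give_minus_68_percent(self):
        """Early 5.6, late 1.8 ppb/degC -> a 67.9% decrease."""
        ch = cp.period_change(self._est(5.6), self._est(1.8))
        assert ch.percent_change == pytest.approx(-67.857, abs=0.01)

    def test_equal_slopes_zero_percent(self):
        ch = cp.period_change(self._est(2.0), self._est(2.0))
        assert ch.percent_change == pytest.approx(0.0)

    def test_nonpositive_early_flagged_undefined(self):
        ch = cp.period_change(self._est(-0.1), self._est(1.0))
        assert ch.undefined and np.isnan(ch.percent_change)

    def test_ci_from_paired_draws_detects_change(self):
        rng = np.random.default_rng(11)
        early = self._est(2.0, draws=rng.normal(2.0, 0.05, 500))
        late = self._est(0.5, draws=rng.normal(0.5, 0.05, 500))
        ch = cp.period_change(early, late)
        assert ch.ci is not None and ch.ci[1] < 0 and ch.significant

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cp.period_change(self._est(1.0, region="SE"), self._est(1.0, region="NE"))


class TestMovingWindows:
    def test_thirteen_windows_for_17_years(self):
        truth = cp.make_truth(seed=13, shape=(4, 4), years=(2000, 2016),
                              scenario="flat", noise_seasonal_sd=0.0)
        f = cp.simulate_fields(truth, variables=("temperature", "pm25"))
        tmean = (f["tmax"] + f["tmin"]) / 2.0
        pm = cp.grid_seasonal_means(f["pm25"], "JJA")
        t = cp.grid_seasonal_means(tmean, "JJA")
        mw = cp.moving_window_sensitivity(pm, t, window_years=5)
        assert len(mw) == 13
        assert mw[0].period == (2000, 2004) and mw[-1].period == (2012, 2016)
        for est in mw:
            assert est.slope == pytest.approx(1.0, abs=1e-9)

    def test_full_span_window_equals_full_record(self, flat_seasonal):
        pm, t = flat_seasonal["pm_jja"], flat_seasonal["t_jja"]
        mw = cp.moving_window_sensitivity(pm, t, window_years=9)
        full = cp.regional_sensitivity(
            cp.pool_region_anomalies(cp.period_anomalies(pm, t), None))
        assert len(mw) == 1
        assert mw[0].slope == pytest.approx(full.slope, rel=1e-12)

    def test_window_longer_than_record_rejected(self, flat_seasonal):
        with pytest.raises(ValueError, match="window"):
            cp.moving_window_sensitivity(flat_seasonal["pm_jja"], flat_seasonal["t_jja"],
                                         window_years=20)

    def test_stationary_beta_windows_scatter_without_trend(self):
        """With a constant true beta, 5-year window slopes show no monotone drift."""
        from scipy import stats
        slopes_trend_p = []
        for seed in range(5):
            truth = cp.make_truth(seed=seed, shape=(6, 6), years=(2000, 2016),
                                  scenario="flat", noise_seasonal_sd=0.3)
            f = cp.simulate_fields(truth, variables=("temperature", "pm25"))
            tmean = (f["tmax"] + f["tmin"]) / 2.0
            mw = cp.moving_window_sensitivity(
                cp.grid_seasonal_means(f["pm25"], "JJA"),
                cp.grid_seasonal_means(tmean, "JJA"), window_years=5)
            s = np.array([e.slope for e in mw])
            tau, p = stats.kendalltau(np.arange(len(s)), s)
            slopes_trend_p.append(p)
        assert np.median(slopes_trend_p) > 0.05
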