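"""Monthly climatology, standardisation, correlation maps and series."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy import stats

from mldchl import compositing
from mldchl.anomalies import (correlation_map, lagged_correlation,
                              monthly_climatology, region_anomaly_series,
                              seasonal_window_correlation, standardise)
from mldchl.compositing import CompositeGrid, make_composites
from mldchl.synthetic import SyntheticConfig, generate_fields

from conftest import make_grid


def composite_of(values, start="2003-01-01", name="anom", window=1):
    g = make_grid(values, start=start, name=name)
    return make_composites(g, window=window)


class TestMonthlyClimatology:
    def test_constant_field_flagged_undefined(self):
        cg = composite_of(np.full((60, 1, 1), 5.0))
        clim = monthly_climatology(cg)
        assert not clim.defined.values.any()
        anom = standardise(cg, clim)
        assert np.isnan(anom.data.values).all()

    def test_two_januaries_hand_computed(self):
        # Jan 2003 value 1, Jan 2004 value 3 on a single pixel
        time = pd.DatetimeIndex(["2003-01-05", "2004-01-05"])
        da = xr.DataArray(np.array([1.0, 3.0]).reshape(2, 1, 1),
                          dims=("time", "lat", "lon"),
                          coords={"time": time, "lat": [10.0], "lon": [35.0]},
                          name="mld")
        cg = CompositeGrid(da, xr.ones_like(da, dtype=int), window_days=1)
        clim = monthly_climatology(cg)
        assert clim.mean.sel(month=1).values[0, 0] == pytest.approx(2.0)
        # sample std with ddof=1: sqrt(((1-2)^2+(3-2)^2)/1) = sqrt(2)
        assert clim.std.sel(month=1).values[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_single_sample_month_flagged(self):
        cg = composite_of(np.arange(1.0, 11.0).reshape(10, 1, 1))
        clim = monthly_climatology(cg, min_count=2)
        # only one January month of data => count 10 but a well-defined std;
        # shrink to 1 sample by slicing a single day
        one = composite_of(np.array([[[4.0]]]))
        clim1 = monthly_climatology(one)
        assert not clim1.defined.values.any()
        assert clim.defined.values.all()


class TestStandardise:
    def _cg(self, years=4, pixel_value=None, seed=0):
        rng = np.random.default_rng(seed)
        time = pd.date_range("2003-01-01", periods=365 * years, freq="D")
        vals = rng.normal(10.0, 2.0, (len(time), 1, 1))
        da = xr.DataArray(vals, dims=("time", "lat", "lon"),
                          coords={"time": time, "lat": [10.0], "lon": [35.0]},
                          name="mld")
        return CompositeGrid(da, xr.ones_like(da, dtype=int), window_days=1)

    def test_value_at_mean_gives_zero_and_one_std_gives_one(self):
        cg = self._cg()
        clim = monthly_climatology(cg)
        mu = clim.mean.sel(month=1).values[0, 0]
        sd = clim.std.sel(month=1).values[0, 0]
        probe = cg.data.copy()
        probe.values[0, 0, 0] = mu
        probe.values[1, 0, 0] = mu + sd
        cg2 = CompositeGrid(probe, cg.counts, window_days=1)
        anom = standardise(cg2, clim)
        assert anom.data.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert anom.data.values[1, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_training_data_per_month_mean_zero(self):
        cg = self._cg(seed=3)
        anom = standardise(cg, monthly_climatology(cg))
        months = anom.start_dates.month
        for m in range(1, 13):
            sel = anom.data.values[months == m, 0, 0]
            assert np.nanmean(sel) == pytest.approx(0.0, abs=1e-10)

    def test_missing_propagates_and_no_inf(self):
        cg = self._cg()
        vals = cg.data.values.copy()
        vals[5, 0, 0] = np.nan
        da = cg.data.copy(data=vals)
        cnt = cg.counts.copy()
        cnt.values[5, 0, 0] = 0
        anom = standardise(CompositeGrid(da, cnt, window_days=1),
                           monthly_climatology(cg))
        assert np.isnan(anom.data.values[5, 0, 0])
        assert not np.isinf(anom.data.values).any()


class TestCorrelationMap:
    def _pair(self, n=120, ny=3, nx=3, rho=0.5, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, ny, nx))
        b = rho * a + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, (n, ny, nx))
        time = pd.date_range("2003-01-01", periods=n, freq="4D")
        coords = {"time": time, "lat": np.arange(ny) + 10.0,
                  "lon": np.arange(nx) + 35.0}
        mk = lambda v: xr.DataArray(v, dims=("time", "lat", "lon"), coords=coords)
        return mk(a), mk(b)

    def test_self_correlation_is_one(self):
        a, _ = self._pair()
        cm = correlation_map(a, a, min_pairs=10)
        np.testing.assert_allclose(cm.r.values, 1.0, atol=1e-12)

    def test_p_matches_independent_t_formula(self):
        a, b = self._pair(n=10)
        cm = correlation_map(a, b, min_pairs=3)
        for iy in range(3):
            for ix in range(3):
                x, y = a.values[:, iy, ix], b.values[:, iy, ix]
                r = np.corrcoef(x, y)[0, 1]
                t = r * np.sqrt(8) / np.sqrt(1 - r ** 2)
                p = 2 * (1 - stats.t.cdf(abs(t), 8))
                assert cm.r.values[iy, ix] == pytest.approx(r, abs=1e-10)
                assert cm.p.values[iy, ix] == pytest.approx(p, abs=1e-10)

    def test_pixels_under_pair_gate_masked(self):
        a, b = self._pair(n=120)
        av = a.values.copy()
        av[50:, 0, 0] = np.nan  # 50 valid pairs at that pixel
        a2 = a.copy(data=av)
        cm = correlation_map(a2, b, min_pairs=100)
        assert np.isnan(cm.r.values[0, 0])
        assert cm.n.values[0, 0] == 50
        assert np.isfinite(cm.r.values[1:, :]).all()

    def test_misaligned_grids_rejected(self):
        a, b = self._pair(n=20)
        with pytest.raises(ValueError, match="misaligned"):
            correlation_map(a, b.isel(time=slice(0, 10)))

    def test_null_fields_give_about_five_percent_significant(self):
        # independent anomalies: the p<0.05 rate across pixels is Binomial
        rng = np.random.default_rng(99)
        n, ny, nx = 200, 20, 20
        time = pd.date_range("2003-01-01", periods=n, freq="4D")
        coords = {"time": time, "lat": np.arange(ny) + 10.0,
                  "lon": np.arange(nx) + 30.0}
        a = xr.DataArray(rng.normal(0, 1, (n, ny, nx)),
                         dims=("time", "lat", "lon"), coords=coords)
        b = xr.DataArray(rng.normal(0, 1, (n, ny, nx)),
                         dims=("time", "lat", "lon"), coords=coords)
        cm = correlation_map(a, b, min_pairs=100)
        frac = float(cm.significant.values.mean())
        # 4-sigma binomial band around 0.05 for 400 pixels
        band = 4 * np.sqrt(0.05 * 0.95 / (ny * nx))
        assert abs(frac - 0.05) < band


class TestRegionSeries:
    def _anom(self, vals, start="2003-01-01"):
        return composite_of(np.asarray(vals, dtype=float), start=start)

    def _mask(self, ny, nx, sel=None):
        m = np.zeros((ny, nx), dtype=bool) if sel is not None else np.ones((ny, nx), bool)
        if sel is not None:
            m[sel] = True
        return xr.DataArray(m, dims=("lat", "lon"),
                            coords={"lat": np.arange(ny) + 10.0,
                                    "lon": np.arange(nx) + 35.0})

    def test_uniform_field_gives_constant_series(self):
        cg = self._anom(np.full((5, 2, 2), 2.0))
        s = region_anomaly_series(cg, self._mask(2, 2))
        np.testing.assert_allclose(s.values, 2.0)

    def test_low_coverage_composite_dropped(self):
        vals = np.full((3, 10, 2), 1.0)
        vals[1, :, :] = np.nan
        vals[1, 0, 0] = 1.0  # 1 of 20 pixels -> 5% coverage on composite 1
        s = region_anomaly_series(self._anom(vals), self._mask(10, 2),
                                  min_coverage=0.10)
        assert np.isnan(s.values[1]) and np.isfinite(s.values[[0, 2]]).all()

    def test_checkerboard_averages_to_zero(self):
        vals = np.zeros((1, 4, 4))
        vals[0] = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
        s = region_anomaly_series(self._anom(vals), self._mask(4, 4))
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_masked_pixels_do_not_change_series(self):
        vals = np.full((4, 3, 3), np.nan)
        vals[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        cg = self._anom(vals)
        small = region_anomaly_series(cg, self._mask(3, 3, (0, 0)), 0.0)
        big = region_anomaly_series(cg, self._mask(3, 3), 0.0)
        np.testing.assert_allclose(small.values, big.values)

    def test_empty_region_rejected(self):
        cg = self._anom(np.ones((2, 2, 2)))
        empty = self._mask(2, 2, sel=np.zeros((2, 2), bool))
        empty.values[:] = False
        with pytest.raises(ValueError, match="region"):
            region_anomaly_series(cg, empty)


class TestLaggedCorrelation:
    def test_shifted_series_peaks_at_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 300)
        idx = pd.date_range("2003-01-01", periods=297, freq="4D")
        a = pd.Series(base[3:], index=idx)      # a leads
        b = pd.Series(base[:-3], index=idx)     # b = a delayed by 3 steps
        df = lagged_correlation(a, b, max_lag=10)
        assert df.attrs["best_lag"] == 3
        assert df.loc[df["lag"] == 3, "r"].iloc[0] == pytest.approx(1.0)

    def test_lag_zero_identical_series(self):
        idx = pd.date_range("2003-01-01", periods=50, freq="4D")
        s = pd.Series(np.random.default_rng(2).normal(0, 1, 50), index=idx)
        df = lagged_correlation(s, s, max_lag=5)
        assert df.loc[df["lag"] == 0, "r"].iloc[0] == pytest.approx(1.0)

    def test_white_noise_calibrated_at_five_percent_per_lag(self):
        # per-lag 5% two-sided critical |r| for n=500 (t-based); across
        # 100 seeds x 11 lags the exceedance rate must sit near 5%
        n = 500
        t_crit = stats.t.ppf(0.975, n - 2)
        r_crit = t_crit / np.sqrt(n - 2 + t_crit ** 2)
        idx = pd.date_range("2003-01-01", periods=n, freq="4D")
        exceed = total = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            a = pd.Series(rng.normal(0, 1, n), index=idx)
            b = pd.Series(rng.normal(0, 1, n), index=idx)
            df = lagged_correlation(a, b, max_lag=10)
            exceed += int((df["r"].abs() >= r_crit).sum())
            total += len(df)
        rate = exceed / total
        band = 4 * np.sqrt(0.05 * 0.95 / total)  # 4-sigma binomial band
        assert abs(rate - 0.05) < band

    def test_insufficient_overlap_flagged(self):
        idx = pd.date_range("2003-01-01", periods=6, freq="4D")
        a = pd.Series([1.0, 2, np.nan, np.nan, np.nan, np.nan], index=idx)
        b = pd.Series(np.arange(6.0), index=idx)
        df = lagged_correlation(a, b, max_lag=2)
        assert df["r"].isna().all()


class TestSeasonalWindowCorrelation:
    def _series(self, vals, start="2002-10-01"):
        idx = pd.date_range(start, periods=len(vals), freq="4D")
        return pd.Series(vals, index=idx)

    def test_identical_series_all_r_one(self):
        s = self._series(np.random.default_rng(0).normal(0, 1, 200))
        df = seasonal_window_correlation(s, s, "OND")
        np.testing.assert_allclose(df["r"].dropna().values, 1.0)

    def test_anticorrelated_series_all_minus_one(self):
        s = self._series(np.random.default_rng(1).normal(0, 1, 200))
        df = seasonal_window_correlation(s, -s, "JFM")
        np.testing.assert_allclose(df["r"].dropna().values, -1.0)

    def test_winter_only_coupling_beats_spring(self):
        """Generator with winter-suppressed CHL noise: OND/JFM correlations
        exceed the AMJ correlations computed for contrast."""
        cfg = SyntheticConfig(lat_min=20.0, lat_max=20.5, lon_min=35.0,
                              lon_max=35.5, cell_deg=0.5,
                              start="2003-01-01", end="2009-12-31",
                              beta=0.6, chl_innov_std=0.25,
                              chl_noise_winter_factor=0.1,
                              missing_base=0.0, seed=5)
        mld, chl, *_ = generate_fields(cfg)
        from mldchl.anomalies import monthly_climatology as mclim, standardise as stdz
        mc = make_composites(mld, window=4)
        cc = make_composites(compositing.log_transform(chl), window=4,
                             log_space=True)
        ma = stdz(mc, mclim(mc))
        ca = stdz(cc, mclim(cc))
        sa = pd.Series(ma.data.values[:, 0, 0], index=ma.start_dates)
        sb = pd.Series(ca.data.values[:, 0, 0], index=ca.start_dates)
        winter_r = pd.concat([
            seasonal_window_correlation(sa, sb, w)["r"] for w in ("OND", "JFM")
        ]).mean()
        spring_r = seasonal_window_correlation(sa, sb, "AMJ")["r"].mean()
        assert winter_r > spring_r
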