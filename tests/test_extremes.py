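"""Percentile threshold climatologies, event detection, compounds, maps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mldchl.extremes import (CompoundEvent, ExtremeEvent,
                             build_threshold_climatology, chl_response_fraction,
                             day_of_year_slot, detect_compound, detect_extremes,
                             event_mean_map)
from mldchl.synthetic import Injection, SyntheticConfig, generate_fields

from conftest import make_grid


def daily_series(values, start="2000-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestDayOfYearSlot:
    def test_non_leap_year_maps_one_to_365(self):
        idx = pd.date_range("2003-01-01", "2003-12-31", freq="D")
        slots = day_of_year_slot(idx)
        assert slots[0] == 1 and slots[-1] == 365 and len(set(slots)) == 365

    def test_leap_day_gets_slot_366_and_march_first_stays_60(self):
        idx = pd.DatetimeIndex(["2004-02-28", "2004-02-29", "2004-03-01",
                                "2003-03-01"])
        np.testing.assert_array_equal(day_of_year_slot(idx), [59, 366, 60, 60])


class TestThresholdClimatology:
    def test_constant_series_all_equal(self):
        s = daily_series(np.full(365 * 3, 7.0))
        tc = build_threshold_climatology(s, 90.0)
        np.testing.assert_allclose(tc.mean, 7.0)
        np.testing.assert_allclose(tc.threshold, 7.0)

    def test_pure_sinusoid_thresholds_track_climatology(self):
        t = np.arange(365 * 4)
        s = daily_series(50.0 + 20.0 * np.sin(2 * np.pi * t / 365.0),
                         start="2001-01-01")
        tc = build_threshold_climatology(s, 90.0)
        # zero interannual spread: the only mean/threshold gap left is the
        # sinusoid's slope across the 11-day pooling window (< 2 m here)
        np.testing.assert_allclose(tc.threshold[:365], tc.mean[:365], atol=2.0)
        assert np.corrcoef(tc.mean[:365],
                           50 + 20 * np.sin(2 * np.pi * np.arange(365) / 365))[0, 1] > 0.999

    def test_iid_noise_exceedance_near_ten_percent(self):
        rng = np.random.default_rng(8)
        s = daily_series(rng.normal(0.0, 1.0, 365 * 30), start="1990-01-01")
        tc = build_threshold_climatology(s, 90.0)
        _, thr = tc.at(s.index)
        frac = float((s.values > thr).mean())
        assert abs(frac - 0.10) < 0.02

    def test_short_record_rejected(self):
        s = daily_series(np.ones(400))
        with pytest.raises(ValueError, match="2 years"):
            build_threshold_climatology(s, 90.0)


class TestDetectExtremes:
    def _noisy_series(self, seed=0, years=5):
        rng = np.random.default_rng(seed)
        t = np.arange(365 * years)
        return daily_series(50 + 20 * np.sin(2 * np.pi * t / 365)
                            + rng.normal(0, 2, len(t)), start="2001-01-01")

    def test_injected_six_day_run_found_once(self):
        s = self._noisy_series()
        tc = build_threshold_climatology(s, 90.0)
        s2 = s.copy()
        s2.loc["2003-06-10":"2003-06-15"] += 30.0  # far above any threshold
        events = detect_extremes(s2, tc, "high", min_duration=4)
        hits = [e for e in events if e.start == pd.Timestamp("2003-06-10")]
        assert len(hits) == 1
        assert hits[0].end == pd.Timestamp("2003-06-15")
        assert hits[0].duration_days == 6

    def test_three_day_run_below_minimum_ignored(self):
        s = self._noisy_series(seed=1)
        tc = build_threshold_climatology(s, 90.0)
        s2 = s.copy()
        s2.loc["2003-06-10":"2003-06-12"] += 30.0
        events = detect_extremes(s2, tc, "high", min_duration=4)
        assert not any(e.start == pd.Timestamp("2003-06-10") for e in events)

    def test_interrupted_runs_stay_separate(self):
        s = self._noisy_series(seed=2)
        tc = build_threshold_climatology(s, 90.0)
        s2 = s.copy()
        s2.loc["2003-06-01":"2003-06-05"] += 30.0
        s2.loc["2003-06-06"] -= 40.0  # one normal day between runs
        s2.loc["2003-06-07":"2003-06-11"] += 30.0
        events = [e for e in detect_extremes(s2, tc, "high", 4)
                  if e.end >= pd.Timestamp("2003-06-01")
                  and e.start <= pd.Timestamp("2003-06-13")]
        assert len(events) == 2
        assert events[0].end == pd.Timestamp("2003-06-05")
        assert events[1].start == pd.Timestamp("2003-06-07")
        assert events[1].end == pd.Timestamp("2003-06-11")

    def test_join_gap_merges_across_short_interruption(self):
        s = self._noisy_series(seed=2)
        tc = build_threshold_climatology(s, 90.0)
        s2 = s.copy()
        s2.loc["2003-06-01":"2003-06-05"] += 30.0
        s2.loc["2003-06-06"] -= 40.0
        s2.loc["2003-06-07":"2003-06-11"] += 30.0
        events = [e for e in detect_extremes(s2, tc, "high", 4, join_gap=1)
                  if e.end >= pd.Timestamp("2003-06-01")
                  and e.start <= pd.Timestamp("2003-06-13")]
        assert len(events) == 1
        assert events[0].end == pd.Timestamp("2003-06-11")

    def test_low_polarity_uses_low_percentile(self):
        s = self._noisy_series(seed=3)
        lo = build_threshold_climatology(s, 10.0)
        s2 = s.copy()
        s2.loc["2004-02-01":"2004-02-06"] -= 30.0
        events = detect_extremes(s2, lo, "low", min_duration=4)
        assert any(e.start == pd.Timestamp("2004-02-01") for e in events)
        with pytest.raises(ValueError, match="percentile"):
            detect_extremes(s2, lo, "high", 4)


class TestChlResponse:
    def _events(self, polarity="high"):
        return [ExtremeEvent("mld", polarity, pd.Timestamp("2003-01-01"),
                             pd.Timestamp("2003-01-10"), 10, 1.0, 1.0)]

    def test_all_days_responding_gives_100(self):
        anom = daily_series(np.full(20, 1.0), start="2003-01-01")
        pct, n = chl_response_fraction(self._events(), anom)
        assert pct == 100.0 and n == 10

    def test_zero_anomaly_gives_0(self):
        anom = daily_series(np.zeros(20), start="2003-01-01")
        assert chl_response_fraction(self._events(), anom)[0] == 0.0

    def test_three_of_ten_days_gives_30(self):
        vals = np.zeros(20)
        vals[[0, 3, 7]] = 0.7
        anom = daily_series(vals, start="2003-01-01")
        assert chl_response_fraction(self._events(), anom)[0] == pytest.approx(30.0)

    def test_shallow_events_use_negative_threshold(self):
        vals = np.zeros(20)
        vals[:5] = -0.8
        anom = daily_series(vals, start="2003-01-01")
        pct, _ = chl_response_fraction(self._events("low"), anom)
        assert pct == pytest.approx(50.0)

    def test_boundary_strict_vs_inclusive(self):
        vals = np.full(20, 0.5)  # exactly at the threshold
        anom = daily_series(vals, start="2003-01-01")
        assert chl_response_fraction(self._events(), anom)[0] == 0.0
        assert chl_response_fraction(self._events(), anom,
                                     inclusive=True)[0] == 100.0

    def test_no_event_days_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            chl_response_fraction([], daily_series(np.zeros(5)))


class TestCompound:
    def _ev(self, var, pol, start, end):
        s, e = pd.Timestamp(start), pd.Timestamp(end)
        return ExtremeEvent(var, pol, s, e, (e - s).days + 1, 1.0, 1.0)

    def test_overlap_interval_is_intersection(self):
        deep = self._ev("mld", "high", "2003-01-10", "2003-01-17")
        high = self._ev("chl", "high", "2003-01-15", "2003-01-19")
        out = detect_compound([deep], [high])
        assert len(out) == 1
        assert out[0].overlap_start == pd.Timestamp("2003-01-15")
        assert out[0].overlap_end == pd.Timestamp("2003-01-17")
        assert out[0].klass == "deep-high"

    def test_sign_mismatch_is_not_compound(self):
        deep = self._ev("mld", "high", "2003-01-10", "2003-01-17")
        low = self._ev("chl", "low", "2003-01-15", "2003-01-19")
        assert detect_compound([deep], [low]) == []

    def test_symmetry_of_overlap_sets(self):
        mlds = [self._ev("mld", "high", "2003-01-10", "2003-01-17"),
                self._ev("mld", "low", "2003-03-01", "2003-03-08")]
        chls = [self._ev("chl", "high", "2003-01-16", "2003-01-20"),
                self._ev("chl", "low", "2003-03-05", "2003-03-06")]
        fwd = detect_compound(mlds, chls)
        rev = detect_compound(chls, mlds)
        fwd_set = {(c.overlap_start, c.overlap_end) for c in fwd}
        rev_set = {(c.overlap_start, c.overlap_end) for c in rev}
        assert fwd_set == rev_set and len(fwd) == 2


class TestEventMeanMap:
    def test_single_day_event_equals_that_day(self):
        vals = np.random.default_rng(0).normal(0, 1, (5, 2, 2))
        g = make_grid(vals, name="anom", units="1")
        m = event_mean_map(g, pd.Timestamp("2003-01-03"),
                           pd.Timestamp("2003-01-03"))
        np.testing.assert_allclose(m.values, vals[2])

    def test_uniform_anomaly_maps_to_uniform_mean(self):
        g = make_grid(np.full((6, 2, 2), 2.0), name="anom", units="1")
        m = event_mean_map(g, pd.Timestamp("2003-01-02"),
                           pd.Timestamp("2003-01-04"))
        np.testing.assert_allclose(m.values, 2.0)

    def test_three_day_stack_matches_hand_average(self):
        vals = np.array([[[1.0, 2.0]], [[3.0, np.nan]], [[5.0, 6.0]]])
        g = make_grid(vals, name="anom", units="1")
        m = event_mean_map(g, pd.Timestamp("2003-01-01"),
                           pd.Timestamp("2003-01-03"))
        np.testing.assert_allclose(m.values, [[3.0, 4.0]])

    def test_no_overlap_rejected(self):
        g = make_grid(np.ones((3, 1, 1)), name="anom", units="1")
        with pytest.raises(ValueError, match="overlap"):
            event_mean_map(g, pd.Timestamp("2010-01-01"),
                           pd.Timestamp("2010-01-05"))


class TestEndToEndInjectionRecovery:
    def _detect_on_generator(self, seed, inject_start="2004-12-05",
                             duration=6, amplitude=3.5):
        inj = Injection("mld", 1, inject_start, duration, amplitude)
        cfg = SyntheticConfig(lat_min=20.0, lat_max=21.0, lon_min=35.0,
                              lon_max=36.0, cell_deg=0.5,
                              start="2002-01-01", end="2006-12-31",
                              missing_base=0.0, injections=(inj,), seed=seed)
        mld, *_ = generate_fields(cfg)
        s = pd.Series(mld.data.mean(("lat", "lon")).values, index=mld.time)
        tc = build_threshold_climatology(s, 90.0)
        return detect_extremes(s, tc, "high", min_duration=4)

    def test_injected_event_recovered_with_tight_boundaries(self):
        events = self._detect_on_generator(seed=0)
        t0, t1 = pd.Timestamp("2004-12-05"), pd.Timestamp("2004-12-10")
        near = [e for e in events
                if abs((e.start - t0).days) <= 1 and abs((e.end - t1).days) <= 1]
        assert len(near) == 1

    def test_compounds_recovered_from_co_injections(self):
        injs = (Injection("mld", 1, "2004-12-05", 6, 3.5),
                Injection("chl", 1, "2004-12-07", 5, 3.5),
                Injection("mld", -1, "2005-02-10", 6, 3.5),
                Injection("chl", -1, "2005-02-11", 4, 3.5))
        cfg = SyntheticConfig(lat_min=20.0, lat_max=21.0, lon_min=35.0,
                              lon_max=36.0, cell_deg=0.5,
                              start="2002-01-01", end="2006-12-31",
                              missing_base=0.0, beta=0.0, injections=injs,
                              seed=1)
        mld, chl, *_ = generate_fields(cfg)
        s_m = pd.Series(mld.data.mean(("lat", "lon")).values, index=mld.time)
        logc = np.log10(chl.values).mean(axis=(1, 2))
        s_c = pd.Series(logc, index=chl.time)
        m_up = build_threshold_climatology(s_m, 90.0)
        m_lo = build_threshold_climatology(s_m, 10.0)
        c_up = build_threshold_climatology(s_c, 90.0)
        c_lo = build_threshold_climatology(s_c, 10.0)
        mld_ev = (detect_extremes(s_m, m_up, "high", 4)
                  + detect_extremes(s_m, m_lo, "low", 4))
        chl_ev = (detect_extremes(s_c, c_up, "high", 3)
                  + detect_extremes(s_c, c_lo, "low", 3))
        comps = detect_compound(mld_ev, chl_ev)
        window_hits = {
            c.klass for c in comps
            if pd.Timestamp("2004-12-01") <= c.overlap_start <= pd.Timestamp("2005-02-20")
        }
        assert {"deep-high", "shallow-low"} <= window_hits
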