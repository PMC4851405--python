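"""Preprocessing: day length, resampling, adaptive smoothing, screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import savgol_filter

from savphen import preprocess
from savphen.preprocess import (
    adaptive_savgol,
    aggregate_climate,
    align_site,
    day_length,
    gapfill_resample,
    screen_variables,
)


def noaa_day_length(latitude_deg: float, date: pd.Timestamp) -> float:
    """Independent oracle: NOAA solar-position declination, geometric horizon."""
    doy = pd.Timestamp(date).dayofyear
    g = 2.0 * np.pi / 365.0 * (doy - 1 + 0.5)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    phi = np.deg2rad(latitude_deg)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 * np.arccos(cos_omega) / np.pi


class TestDayLength:
    @pytest.mark.parametrize("date", ["2010-01-01", "2010-06-21", "2010-09-23"])
    def test_equator_always_12h(self, date):
        assert day_length(0.0, date) == pytest.approx(12.0, abs=0.05)

    def test_polar_day_clamped(self):
        assert day_length(80.0, "2010-06-21") == pytest.approx(24.0)
        assert day_length(80.0, "2010-12-21") == pytest.approx(0.0)

    def test_against_noaa_oracle_tonzi(self):
        # mid-latitude site, June solstice
        got = day_length(38.43, "2010-06-21")
        assert got == pytest.approx(noaa_day_length(38.43, "2010-06-21"), abs=0.2)

    @pytest.mark.parametrize("lat", [-35.0, -14.16, 9.82, 38.43, 45.0])
    @pytest.mark.parametrize("date", ["2010-03-01", "2010-06-21", "2010-10-15"])
    def test_against_noaa_oracle_grid(self, lat, date):
        assert day_length(lat, date) == pytest.approx(noaa_day_length(lat, date), abs=0.2)

    def test_hemispheric_symmetry(self):
        north = day_length(30.0, "2010-06-21")
        south = day_length(-30.0, "2010-12-21")
        assert north == pytest.approx(south, abs=0.1)

    def test_vectorized_over_dates(self):
        dates = pd.date_range("2010-01-01", periods=365)
        dl = day_length(45.0, dates)
        assert dl.shape == (365,)
        assert dl.min() > 8 and dl.max() < 16

    def test_bad_latitude(self):
        with pytest.raises(ValueError):
            day_length(91.0, "2010-01-01")


class TestGapfillResample:
    def _frame(self, days, values, start="2005-01-01"):
        start = pd.Timestamp(start)
        return pd.DataFrame(
            {"acq_date": [start + pd.Timedelta(d, "D") for d in days], "ndvi": values}
        )

    def test_midpoint(self):
        dates, vals = gapfill_resample(self._frame([0, 16], [0.2, 0.4]))
        assert len(vals) == 3
        assert vals[1] == pytest.approx(0.3)

    def test_linearity_preserved(self):
        days = [0, 13, 30, 47, 64, 80]
        values = [0.1 + 0.005 * d for d in days]
        dates, vals = gapfill_resample(self._frame(days, values))
        expect = 0.1 + 0.005 * np.arange(0, 81, 8)
        np.testing.assert_allclose(vals, expect, atol=1e-12)

    def test_no_extrapolation(self):
        dates, vals = gapfill_resample(self._frame([0, 20], [0.2, 0.4]))
        # grid stops at or before the last observation (day 20 -> day 16)
        assert (dates[-1] - dates[0]).days == 16

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            gapfill_resample(self._frame([0], [0.5]))

    def test_tracks_latent_series_through_jittered_composites(self):
        # grid values must stay within the latent series' local variation
        rng = np.random.default_rng(0)
        t = np.arange(400, dtype=float)
        latent = 0.45 + 0.25 * np.sin(2 * np.pi * t / 365.0)
        day = np.arange(0, 400 - 16, 16) + rng.integers(0, 9, size=24)
        dates, vals = gapfill_resample(self._frame(day, latent[day]))
        grid_day = (dates - dates[0]).days.to_numpy() + day[0]
        # linear-interpolation error bound: max |f''| * h^2 / 8 over a window
        bound = 0.25 * (2 * np.pi / 365.0) ** 2 * 24.0**2 / 8.0
        assert np.max(np.abs(vals - latent[grid_day])) < bound + 1e-9


class TestAdaptiveSavgol:
    def test_constant_reproduced(self):
        x = np.full(20, 0.3)
        np.testing.assert_allclose(adaptive_savgol(x), x, atol=1e-12)

    def test_quadratic_reproduced(self):
        t = np.arange(30, dtype=float)
        x = 0.2 + 0.01 * t - 0.0003 * t**2
        np.testing.assert_allclose(adaptive_savgol(x), x, atol=1e-10)

    @given(
        coeffs=st.tuples(
            st.floats(-1, 1), st.floats(-0.05, 0.05), st.floats(-0.002, 0.002)
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_polynomial_idempotence_property(self, coeffs):
        a, b, c = coeffs
        t = np.arange(25, dtype=float)
        x = a + b * t + c * t**2
        np.testing.assert_allclose(adaptive_savgol(x), x, atol=1e-8)

    def test_jump_rule_switches_to_small_window(self):
        # step of 0.3 > 0.08: points adjacent to the step keep the 3-point
        # fit, which interpolates them exactly (= raw values)
        x = np.r_[np.full(10, 0.2), np.full(10, 0.5)]
        out = adaptive_savgol(x)
        # the 3-point quadratic through any 3 points is exact at its centre
        for i in (9, 10):
            pfit = np.polyfit([-1, 0, 1], x[i - 1 : i + 2], 2)
            assert out[i] == pytest.approx(np.polyval(pfit, 0.0), abs=1e-12)
            assert out[i] == pytest.approx(x[i], abs=1e-12)
        # far from the step the wide filter applies
        np.testing.assert_allclose(
            out[:6], savgol_filter(x, 7, 2, mode="interp")[:6], atol=1e-12
        )

    def test_small_jump_not_triggered(self):
        x = np.r_[np.full(10, 0.2), np.full(10, 0.25)]  # 0.05 < 0.08
        np.testing.assert_allclose(
            adaptive_savgol(x), savgol_filter(x, 7, 2, mode="interp"), atol=1e-12
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_savgol(np.ones(20), window=6)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            adaptive_savgol(np.ones(5))


class TestAggregateClimate:
    def _climate(self, sm, start="2005-01-01"):
        dates = pd.date_range(start, periods=len(sm), freq="D")
        return pd.DataFrame({"date": dates, "sm_volpct": sm})

    def test_identical_values(self):
        clim = self._climate(np.full(16, 7.0))
        grid = pd.DatetimeIndex(["2005-01-01", "2005-01-09"])
        sm, dayl = aggregate_climate(clim, 10.0, grid)
        np.testing.assert_allclose(sm, [7.0, 7.0])
        dates = pd.date_range("2005-01-01", periods=16)
        dl_daily = day_length(10.0, dates)
        assert dayl[0] == pytest.approx(np.max(dl_daily[:8]))

    def test_median_definition(self):
        clim = self._climate(np.array([1, 2, 3, 4, 5, 6, 7, 100], dtype=float))
        sm, _ = aggregate_climate(clim, 0.0, pd.DatetimeIndex(["2005-01-01"]))
        assert sm[0] == pytest.approx(4.5)

    def test_solstice_window_has_annual_max_daylength(self):
        n = 365
        clim = self._climate(np.full(n, 10.0), start="2005-01-01")
        grid = pd.date_range("2005-01-01", periods=45, freq="8D")
        _, dayl = aggregate_climate(clim, 45.0, pd.DatetimeIndex(grid))
        step_of_max = int(np.argmax(dayl))
        solstice_step = (pd.Timestamp("2005-06-21") - pd.Timestamp("2005-01-01")).days // 8
        assert step_of_max == solstice_step

    def test_empty_window_rejected(self):
        clim = self._climate(np.full(8, 5.0))
        grid = pd.DatetimeIndex(["2005-02-01"])
        with pytest.raises(ValueError):
            aggregate_climate(clim, 0.0, grid)

    def test_hull_preservation(self):
        rng = np.random.default_rng(3)
        sm = rng.uniform(1, 30, 80)
        clim = self._climate(sm)
        grid = pd.date_range("2005-01-01", periods=10, freq="8D")
        agg, _ = aggregate_climate(clim, 20.0, pd.DatetimeIndex(grid))
        assert agg.min() >= sm.min() and agg.max() <= sm.max()


class TestScreenVariables:
    def _sites(self, rng, n_sites=4, n=100):
        ndvi, dayl, tmin, sm = [], [], [], []
        for _ in range(n_sites):
            t = np.arange(n)
            season = np.sin(2 * np.pi * t / 45.0)
            d = 12 + 2 * season + 0.1 * rng.normal(size=n)
            tm = 15 + 5 * season + 2.0 * rng.normal(size=n)  # correlated with dayl
            s = 10 + 3 * np.roll(season, 3) + 3.0 * rng.normal(size=n)
            y = 0.3 + 0.02 * d + 0.02 * s + 0.03 * rng.normal(size=n)
            ndvi.append(y)
            dayl.append(d)
            tmin.append(tm)
            sm.append(s)
        return ndvi, {"dayl": dayl, "tmin": tmin, "sm": sm}

    def test_weaker_member_of_correlated_pair_dropped(self):
        ndvi, cand = self._sites(np.random.default_rng(0))
        report = screen_variables(cand, ndvi, correlation_threshold=0.7)
        assert "tmin" in report.dropped
        assert "dayl" in report.retained and "sm" in report.retained
        assert abs(report.pair_corr.loc["dayl", "tmin"]) > 0.7

    def test_duplicated_variable(self):
        ndvi, cand = self._sites(np.random.default_rng(1))
        dup = {"a": cand["dayl"], "b": cand["dayl"]}
        report = screen_variables(dup, ndvi)
        assert len(report.retained) == 1

    def test_single_variable_passthrough(self):
        ndvi, cand = self._sites(np.random.default_rng(2))
        report = screen_variables({"sm": cand["sm"]}, ndvi)
        assert report.retained == ["sm"]

    def test_constant_series_flagged_and_dropped(self):
        ndvi, cand = self._sites(np.random.default_rng(3))
        cand["flat"] = [np.full_like(x, 3.0) for x in cand["sm"]]
        with pytest.warns(UserWarning):
            report = screen_variables(cand, ndvi)
        assert "flat" in report.dropped


class TestAlignSite:
    def test_grid_alignment_invariant(self, small_raw_ensemble):
        for record in small_raw_ensemble:
            aligned = align_site(record)
            assert len(aligned.ndvi) == len(aligned.sm) == len(aligned.dayl)
            steps = np.diff(aligned.step_dates.to_numpy()).astype("timedelta64[D]")
            assert (steps == np.timedelta64(8, "D")).all()
            assert not np.isnan(aligned.ndvi).any()

    def test_grid_origin_is_first_acquisition(self, small_raw_ensemble):
        record = small_raw_ensemble[0]
        aligned = align_site(record)
        assert aligned.step_dates[0] == pd.to_datetime(record.ndvi["acq_date"].iloc[0])
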