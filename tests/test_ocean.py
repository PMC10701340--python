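"""Season-year cumulation, accumulation windows, climatologies, correlations."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy import stats

from whalemorph import ocean
from whalemorph.synth import ForcingSpec, forcing_window_truth, simulate_forcing


def constant_series(value=1.0, hemisphere="N", years=(2015, 2016)):
    start = pd.Timestamp(years[0], 1 if hemisphere == "N" else 7, 1)
    end = pd.Timestamp(years[-1] + 1, 1 if hemisphere == "N" else 7, 1) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D")
    return ocean.DailySeries(dates, np.full(len(dates), value), hemisphere=hemisphere)


class TestSeasonYearSplit:
    def test_southern_hemisphere_july_start(self):
        dates = pd.DatetimeIndex(["2015-06-30", "2015-07-01"])
        labels = ocean.season_year(dates, "S")
        assert list(labels) == [2014, 2015]

    def test_northern_hemisphere_calendar_year(self):
        dates = pd.DatetimeIndex(["2015-06-30", "2015-12-31", "2016-01-01"])
        assert list(ocean.season_year(dates, "N")) == [2015, 2015, 2016]

    def test_constant_year_running_sum(self):
        curves, excluded = ocean.season_year_split(constant_series())
        assert not excluded
        np.testing.assert_allclose(curves[2015].cumulative, np.arange(1, 366))

    def test_gap_days_contribute_zero_and_are_counted(self):
        s = constant_series()
        keep = ~((s.dates.month == 3) & (s.dates.day <= 10))
        gappy = ocean.DailySeries(s.dates[keep], s.values[keep.nonzero()[0]])
        curves, _ = ocean.season_year_split(gappy)
        c = curves[2015]
        assert c.missing_days == 10
        # final total is 10 less than the complete year
        assert c.cumulative[-1] == 355
        assert np.all(np.diff(c.cumulative) >= 0)

    def test_mostly_missing_year_excluded(self):
        s = constant_series()
        keep = s.dates.month <= 4  # ~1/3 coverage
        sparse = ocean.DailySeries(s.dates[keep], s.values[keep.nonzero()[0]])
        curves, excluded = ocean.season_year_split(sparse, max_missing_fraction=0.5)
        assert excluded == [2015, 2016]

    def test_leap_day_dropped(self):
        dates = pd.date_range("2016-01-01", "2016-12-31", freq="D")
        s = ocean.DailySeries(dates, np.ones(len(dates)))
        curves, _ = ocean.season_year_split(s)
        assert curves[2016].cumulative.shape == (365,)
        assert curves[2016].cumulative[-1] == 365

    def test_hemisphere_relabel_preserves_daily_values(self):
        s = constant_series(hemisphere="N")
        s_south = ocean.DailySeries(s.dates, s.values, hemisphere="S")
        np.testing.assert_array_equal(s.values, s_south.values)
        n_total = sum(
            c.cumulative[-1] for c in ocean.season_year_split(s)[0].values()
        )
        # same data re-binned: totals differ per year but values untouched
        assert n_total == 730


class TestClimatologicalMean:
    def test_idempotent_on_identical_curves(self):
        c = ocean.SeasonYearCurve(2015, np.arange(1.0, 366))
        mean = ocean.climatological_mean([c, ocean.SeasonYearCurve(2016, np.arange(1.0, 366))])
        np.testing.assert_allclose(mean, np.arange(1, 366))

    def test_daywise_arithmetic(self):
        a = ocean.SeasonYearCurve(2015, np.arange(1.0, 366))
        b = ocean.SeasonYearCurve(2016, 2 * np.arange(1.0, 366))
        np.testing.assert_allclose(
            ocean.climatological_mean([a, b]), 1.5 * np.arange(1, 366)
        )

    def test_mean_tracks_generative_expectation(self):
        spec = ForcingSpec(n_years=10, kappa=1.0, noise_sd=0.3, base=1.0, amplitude=50.0)
        s = simulate_forcing(spec, seed=5)
        curves, _ = ocean.season_year_split(s)
        clim = ocean.climatological_mean(curves)
        noiseless = simulate_forcing(
            ForcingSpec(**{**spec.__dict__, "noise_sd": 0.0}), seed=0
        )
        expect = np.cumsum(noiseless.values[:365])
        se = 0.3 * np.sqrt(np.arange(1, 366)) / np.sqrt(10)
        assert np.all(np.abs(clim - expect) <= 3 * se + 1e-9)


class TestAccumulationWindow:
    def test_constant_forcing_interpolated_exactly(self):
        win = ocean.accumulation_window(np.arange(1.0, 366), 0.5)
        assert win.start_day == pytest.approx(91.25)
        assert win.end_day == pytest.approx(273.75)
        assert win.length_days == pytest.approx(182.5)

    def test_single_day_impulse_collapses_to_zero(self):
        daily = np.zeros(365)
        daily[99] = 10.0
        win = ocean.accumulation_window(np.cumsum(daily), 0.5)
        assert win.length_days == 0.0
        assert win.start_day == win.end_day == 100

    def test_vonmises_matches_cdf_inversion(self):
        spec = ForcingSpec(kappa=2.0, noise_sd=0.0, base=0.0, amplitude=100.0, n_years=3)
        s = simulate_forcing(spec, seed=0)
        clim = ocean.climatological_mean(ocean.season_year_split(s)[0])
        win = ocean.accumulation_window(clim, 0.5)
        assert win.length_days == pytest.approx(forcing_window_truth(spec, 0.5), abs=1.0)

    def test_window_nesting_on_random_curves(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            daily = rng.gamma(0.5, size=365)
            c = np.cumsum(daily)
            w50 = ocean.accumulation_window(c, 0.5)
            w80 = ocean.accumulation_window(c, 0.8)
            assert w80.start_day <= w50.start_day <= w50.end_day <= w80.end_day

    def test_window_shrinks_with_concentration(self):
        lengths = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            spec = ForcingSpec(kappa=kappa, noise_sd=0.0, base=0.0, amplitude=100.0, n_years=2)
            clim = ocean.climatological_mean(
                ocean.season_year_split(simulate_forcing(spec, seed=0))[0]
            )
            lengths.append(ocean.accumulation_window(clim, 0.5).length_days)
        assert all(a > b for a, b in zip(lengths, lengths[1:]))

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ocean.UndefinedWindow):
            ocean.accumulation_window(np.cumsum(-np.ones(365)), 0.5)

    def test_day_labels_round_half_up(self):
        win = ocean.AccumulationWindow(0.5, 91.25, 273.75)
        assert (win.start_label, win.end_label) == (91, 274)


class TestUpwellingIndex:
    def test_sign_convention(self):
        dates = pd.date_range("2015-01-01", periods=3)
        near = ocean.DailySeries(dates, np.full(3, 16.0))
        off = ocean.DailySeries(dates, np.full(3, 18.0))
        idx = ocean.upwelling_index_sst(near, off)
        np.testing.assert_allclose(idx.values, 2.0)
        rev = ocean.upwelling_index_sst(near, off, positive_when_nearshore_colder=False)
        np.testing.assert_allclose(rev.values, -2.0)

    def test_identical_series_zero(self):
        dates = pd.date_range("2015-01-01", periods=5)
        s = ocean.DailySeries(dates, np.arange(5.0))
        np.testing.assert_allclose(ocean.upwelling_index_sst(s, s).values, 0.0)

    def test_date_mismatch_rejected(self):
        a = ocean.DailySeries(pd.date_range("2015-01-01", periods=3), np.ones(3))
        b = ocean.DailySeries(pd.date_range("2015-01-02", periods=3), np.ones(3))
        with pytest.raises(ocean.DateMismatch):
            ocean.upwelling_index_sst(a, b)


class TestBoxAverage:
    def make_field(self, values):
        return xr.DataArray(
            values,
            dims=("time", "lat", "lon"),
            coords={
                "time": pd.date_range("2015-01-01", periods=values.shape[0]),
                "lat": np.linspace(-45, -42, values.shape[1]),
                "lon": np.linspace(-75, -73, values.shape[2]),
            },
        )

    def test_uniform_field(self):
        da = self.make_field(np.full((4, 5, 5), 5.0))
        out = ocean.box_average(da, (-45, -42), (-75, -73))
        np.testing.assert_allclose(out.values, 5.0)

    def test_2x2_arithmetic(self):
        da = self.make_field(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        out = ocean.box_average(da, (-45, -42), (-75, -73))
        assert out.values[0] == pytest.approx(2.5)

    def test_missing_cells_excluded(self):
        vals = np.full((2, 2, 2), 4.0)
        vals[:, 0, 0] = np.nan
        out = ocean.box_average(self.make_field(vals), (-45, -42), (-75, -73))
        np.testing.assert_allclose(out.values, 4.0)

    def test_empty_intersection_rejected(self):
        da = self.make_field(np.ones((1, 3, 3)))
        with pytest.raises(ValueError):
            ocean.box_average(da, (10, 20), (-75, -73))

    def test_netcdf3_round_trip(self, tmp_path):
        da = self.make_field(np.random.default_rng(0).normal(size=(3, 4, 4)))
        path = tmp_path / "field.nc"
        da.to_dataset(name="sst").to_netcdf(path, engine="scipy")
        ds = ocean.open_gridded(path)
        out = ocean.box_average(ds["sst"], (-45, -42), (-75, -73))
        np.testing.assert_allclose(out.values, da.mean(dim=("lat", "lon")).values, rtol=1e-6)


class TestMonthlyClimatology:
    def test_identical_years(self):
        idx = pd.date_range("2015-01-01", periods=24, freq="MS")
        vals = np.tile(np.arange(1.0, 13.0), 2)
        clim = ocean.monthly_climatology(pd.Series(vals, index=idx))
        np.testing.assert_allclose(clim.monthly_mean, np.arange(1, 13))

    def test_january_mean(self):
        idx = pd.DatetimeIndex(
            [f"2015-{m:02d}-01" for m in range(1, 13)] + ["2016-01-01"]
        )
        vals = np.array([1.0] + [5.0] * 11 + [3.0])
        clim = ocean.monthly_climatology(pd.Series(vals, index=idx))
        assert clim.monthly_mean[0] == pytest.approx(2.0)

    def test_peak_month_recovered_under_noise(self):
        rng = np.random.default_rng(23)
        hits = 0
        months = pd.date_range("2012-01-01", periods=8 * 12, freq="MS")
        cycle = 2 + np.cos(2 * np.pi * (months.month - 1) / 12)  # peak January
        # noise sd chosen so adjacent months (0.13 apart in the cycle) are
        # separable after 8 years of averaging; larger noise has no power
        for _ in range(200):
            series = pd.Series(cycle + rng.normal(0, 0.1, len(months)), index=months)
            hits += ocean.monthly_climatology(series).peak_month == 1
        assert hits / 200 >= 0.95


class TestSalinityChlCorrelation:
    def test_perfect_correlations(self):
        idx = pd.date_range("2013-01-01", periods=10)
        x = pd.Series(np.arange(10.0), index=idx)
        assert ocean.salinity_chl_correlation(x, x)[0] == pytest.approx(1.0)
        assert ocean.salinity_chl_correlation(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        idx = pd.date_range("2013-01-01", periods=5)
        x = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        y = pd.Series([2.0, 1, 3, 5, 4], index=idx)
        r, p = ocean.salinity_chl_correlation(x, y)
        # hand product-moment: cov=1.6, sx=sy=sqrt(2) -> r=0.8
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(stats.pearsonr(x, y).pvalue)

    def test_zero_variance_rejected(self):
        idx = pd.date_range("2013-01-01", periods=5)
        with pytest.raises(ValueError):
            ocean.salinity_chl_correlation(
                pd.Series(np.ones(5), index=idx), pd.Series(np.arange(5.0), index=idx)
            )
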