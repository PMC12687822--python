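"""Seasonal averages, circular season diameter/midpoint, exclusion mask."""

import numpy as np
import pandas as pd
import pytest

from vectorhab.grid_io import GridSpec, risk_stack
from vectorhab.seasonality import (
    SeasonProfile,
    annual_series,
    circular_doy_distance,
    exclusion_mask,
    historical_difference,
    period_average,
    season_diameter,
    season_midpoint,
    season_profile_map,
    seasonal_average,
    transition_change,
    transition_difference,
)

GRID = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=2, n_lon=2)


def stack_from_values(dates, values_by_day):
    """values_by_day: (n_days,) broadcast over a 2x2 grid."""
    arr = np.repeat(np.asarray(values_by_day, dtype=float)[:, None, None], 2, 1)
    arr = np.repeat(arr, 2, 2)
    return risk_stack(GRID, dates, arr)


def brute_force_diameter(series, mass=0.95):
    """Independent O(365^2) oracle: scan every circular start/length."""
    s = np.nan_to_num(np.asarray(series, float), nan=0.0)
    total = s.sum()
    target = mass * total
    doubled = np.concatenate([s, s])
    best_d, best_start = 366, -1
    for start in range(365):
        c = np.cumsum(doubled[start:start + 365])
        hit = np.nonzero(c >= target)[0]
        L = int(hit[0]) + 1 if hit.size else 365
        if L < best_d:
            best_d, best_start = L, start
    return best_d, best_start


class TestAverages:
    def test_constant_stack_mean(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        st = stack_from_values(dates, np.full(len(dates), 0.4))
        np.testing.assert_allclose(period_average(st), 0.4, atol=1e-6)

    def test_two_day_mean(self):
        st = stack_from_values(pd.date_range("2022-01-01", periods=2), [0.2, 0.4])
        np.testing.assert_allclose(period_average(st), 0.3)

    def test_missing_days_ignored(self):
        arr = np.full((3, 2, 2), 0.2)
        arr[1] = np.nan
        st = risk_stack(GRID, pd.date_range("2022-01-01", periods=3), arr)
        np.testing.assert_allclose(period_average(st), 0.2)

    def test_seasonal_average_day_count_weighting(self):
        # per-month constants: weighted mean by month lengths
        dates = pd.date_range("2022-01-01", "2022-12-31")
        vals = dates.month / 12.0
        st = stack_from_values(dates, vals)
        # MAM: Mar(31)*3 + Apr(30)*4 + May(31)*5 over 92 days, /12
        expected = (31 * 3 + 30 * 4 + 31 * 5) / 92 / 12
        np.testing.assert_allclose(seasonal_average(st, "MAM", 2022), expected, atol=1e-6)

    def test_jja_of_constant_stack(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        st = stack_from_values(dates, np.full(len(dates), 0.5))
        np.testing.assert_allclose(seasonal_average(st, "JJA", 2022), 0.5)

    def test_djf_spans_year_boundary(self):
        dates = pd.date_range("2021-12-01", "2022-03-01")
        vals = np.where(pd.DatetimeIndex(dates).year == 2021, 0.9, 0.3)
        st = stack_from_values(dates, vals)
        # DJF 2022 = Dec 2021 (31 d of 0.9) + Jan (31 d) + Feb (28 d) of 0.3
        expected = (31 * 0.9 + 59 * 0.3) / 90
        np.testing.assert_allclose(seasonal_average(st, "DJF", 2022), expected, atol=1e-6)

    def test_transition_difference_and_antisymmetry(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        vals = np.where(pd.DatetimeIndex(dates).month.isin([6, 7, 8]), 0.6, 0.2)
        st = stack_from_values(dates, vals)
        np.testing.assert_allclose(transition_difference(st, "MAM", "JJA", 2022), 0.4, atol=1e-6)
        np.testing.assert_allclose(
            transition_difference(st, "MAM", "JJA", 2022),
            -transition_difference(st, "JJA", "MAM", 2022))

    def test_historical_difference(self):
        dates = pd.date_range("2022-01-01", periods=10)
        recent = stack_from_values(dates, np.full(10, 0.5))
        base = stack_from_values(dates, np.full(10, 0.4))
        np.testing.assert_allclose(historical_difference(recent, base), 0.1, atol=1e-6)

    def test_transition_change_sign_convention(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        month = pd.DatetimeIndex(dates).month
        sharp = stack_from_values(dates, np.where(month.isin([6, 7, 8]), 0.8, 0.1))
        mild = stack_from_values(dates, np.where(month.isin([6, 7, 8]), 0.4, 0.3))
        out = transition_change(sharp, mild, "MAM", "JJA", 2022, 2022)
        assert (out > 0).all()  # recent sharper -> diversification -> positive
        np.testing.assert_allclose(
            transition_change(sharp, sharp, "MAM", "JJA", 2022, 2022), 0.0)


class TestSeasonDiameter:
    def test_boxcar_needs_95_of_100_days(self):
        s = np.zeros(365)
        s[99:199] = 0.7
        d, start = season_diameter(s)
        assert d == 95
        assert start == 99

    def test_constant_series_diameter_347(self):
        d, _ = season_diameter(np.full(365, 0.2))
        assert d == int(np.ceil(0.95 * 365)) == 347

    def test_wraparound_boxcar_crosses_year_boundary(self):
        s = np.zeros(365)
        s[348:] = 1.0   # Dec 15 .. Dec 31
        s[:15] = 1.0    # Jan 1 .. Jan 15
        d, start = season_diameter(s)
        assert d == int(np.ceil(0.95 * 32)) == 31
        assert start >= 348  # window starts in December, wraps

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(0)
        for i in range(200):
            kind = i % 4
            if kind == 0:
                s = rng.uniform(0, 1, 365)
            elif kind == 1:  # sparse spikes
                s = np.zeros(365)
                s[rng.choice(365, 12, replace=False)] = rng.uniform(0.1, 1, 12)
            elif kind == 2:  # boxcar, possibly wrapping
                s = np.zeros(365)
                start = int(rng.integers(0, 365))
                length = int(rng.integers(5, 200))
                s[(start + np.arange(length)) % 365] = rng.uniform(0.2, 1)
            else:  # smooth seasonal bump
                doy = np.arange(365)
                s = np.clip(np.sin(2 * np.pi * (doy - rng.integers(0, 365)) / 365), 0, None)
            if s.sum() == 0:
                continue
            assert season_diameter(s) == brute_force_diameter(s)

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            season_diameter(np.zeros(365))

    def test_scaling_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 1, 365)
        assert season_diameter(s) == season_diameter(10.0 * s)
        assert season_midpoint(s) == season_midpoint(10.0 * s)

    def test_diameter_non_increasing_in_mass(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0, 1, 365)
        diams = [season_diameter(s, m)[0] for m in (0.95, 0.8, 0.5, 0.2, 0.01)]
        assert all(a >= b for a, b in zip(diams, diams[1:]))

    def test_tiny_mass_isolates_unique_maximum(self):
        s = np.full(365, 0.01)
        s[200] = 5.0
        d, start = season_diameter(s, mass=0.5)
        assert d == 1 and start == 200


class TestSeasonMidpoint:
    def test_symmetric_boxcar(self):
        s = np.zeros(365)
        s[99:199] = 0.7  # days 100..199
        assert season_midpoint(s) in (149, 150)

    def test_single_spike_is_the_spike_day(self):
        s = np.zeros(365)
        s[200] = 1.0
        assert season_midpoint(s) == 201

    def test_wraparound_boxcar_midpoint_near_jan1(self):
        s = np.zeros(365)
        s[349:] = 1.0
        s[:16] = 1.0
        mid = season_midpoint(s)
        assert circular_doy_distance(mid, 1.0) <= 2


class TestAnnualSeries:
    def test_leap_day_folded_into_day_59(self):
        dates = pd.date_range("2024-01-01", "2024-12-31")  # leap year
        vals = np.zeros(len(dates))
        vals[58] = 0.2   # Feb 28
        vals[59] = 0.6   # Feb 29
        vals[60] = 0.4   # Mar 1
        st = stack_from_values(dates, vals)
        series = annual_series(st, 2024)
        assert series.shape[0] == 365
        assert series[58, 0, 0] == pytest.approx(0.4)  # mean of Feb 28/29
        assert series[59, 0, 0] == pytest.approx(0.4)  # Mar 1 shifted back
        assert np.nansum(series[:, 0, 0]) == pytest.approx(0.2 / 2 + 0.6 / 2 + 0.4)

    def test_non_leap_year_passthrough(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        vals = np.linspace(0, 1, len(dates))
        st = stack_from_values(dates, vals)
        series = annual_series(st, 2022)
        np.testing.assert_allclose(series[:, 0, 0], vals)


class TestProfileAndExclusion:
    @pytest.fixture
    def profile(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        doy = np.arange(len(dates))
        arr = np.zeros((len(dates), 2, 2))
        arr[:, 0, 0] = np.where((doy >= 99) & (doy < 199), 0.7, 0.0)  # summer cell
        arr[:, 0, 1] = np.where((doy >= 350) | (doy < 10), 0.5, 0.0)  # Jan-1 season
        arr[:, 1, 0] = 0.3                                            # year-round
        # arr[:,1,1] stays all-zero: degenerate
        return season_profile_map(risk_stack(GRID, dates, arr), 2022)

    def test_profile_values(self, profile):
        assert profile.diameter[0, 0] == 95
        assert profile.seasonality[0, 0] == pytest.approx(1 / 95)
        assert profile.diameter[1, 0] == 347
        assert np.isnan(profile.diameter[1, 1])
        assert profile.midpoint[0, 0] in (149, 150)

    def test_exclusion_masks_jan1_and_degenerate_cells(self, profile):
        masked, (lo, hi) = exclusion_mask(profile)
        assert masked[0, 1]        # midpoint within 10 days of Jan 1
        assert masked[1, 1]        # degenerate
        assert not masked[0, 0]
        assert not masked[1, 0]
        assert lo <= hi

    def test_circular_distance(self):
        assert circular_doy_distance(360.0) == 6.0
        assert circular_doy_distance(180.0) == 179.0
        assert circular_doy_distance(1.0) == 0.0

    def test_percentile_clip_range_order_statistics(self):
        prof = SeasonProfile(
            diameter=np.ones((10, 10)),
            seasonality=np.arange(1.0, 101.0).reshape(10, 10),
            midpoint=np.full((10, 10), 180.0),
            total_mass=np.ones((10, 10)))
        _, (lo, hi) = exclusion_mask(prof)
        np.testing.assert_allclose([lo, hi], np.percentile(np.arange(1.0, 101.0), [2, 98]))
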