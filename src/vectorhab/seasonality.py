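"""Temporal analytics on daily FNR stacks.

Period and seasonal averages, seasonal-transition maps, the circular
season-diameter/seasonality score, season midpoints, historical difference
maps, and the visualization exclusion heuristic.

The season diameter *d* of a location is the length of the smallest
*circular* window of days (wrapping December into January) whose FNR sum
reaches 95% of the year's cumulative FNR; seasonality is reported as 1/d,
so sharper seasons score higher.  The midpoint is the first day, within
that window, at which half of the window's FNR mass has accumulated.

Leap days: series are always length 365; Feb 29 is folded into the Feb 28
bucket (day-of-year 59) by averaging the two days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

SEASON_MONTHS = {
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
    "DJF": (12, 1, 2),
}


@dataclass
class SeasonProfile:
    """Per-cell season geometry for one year; NaN marks degenerate cells."""

    diameter: np.ndarray      # days, 1..365
    seasonality: np.ndarray   # 1/diameter, day^-1
    midpoint: np.ndarray      # day-of-year, 1..365
    total_mass: np.ndarray    # cumulative FNR over the year
    mass: float = 0.95
    year: int | None = None


# ---------------------------------------------------------------------------
# averages and differences
# ---------------------------------------------------------------------------

def period_average(stack: xr.DataArray, date_range=None) -> np.ndarray:
    """Per-cell mean FNR over the date range (NaN days ignored; all-missing
    cells stay NaN)."""
    sel = stack
    if date_range is not None:
        sel = stack.sel(time=slice(pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])))
    with np.errstate(invalid="ignore"):
        return sel.mean(dim="time", skipna=True).values


def _season_dates(season: str, years) -> pd.DatetimeIndex:
    """All dates in the season across the given years.

    DJF of year y is Dec(y-1) + Jan(y) + Feb(y).
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; expected one of {list(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    dates = []
    for y in np.atleast_1d(years):
        y = int(y)
        for m in months:
            yy = y - 1 if (season == "DJF" and m == 12) else y
            dates.append(pd.date_range(f"{yy}-{m:02d}-01", periods=1, freq="MS"))
            dates[-1] = pd.date_range(dates[-1][0], dates[-1][0] + pd.offsets.MonthEnd(0), freq="D")
    return pd.DatetimeIndex(np.concatenate([d.values for d in dates])).sort_values()


def seasonal_average(stack: xr.DataArray, season: str, years) -> np.ndarray:
    """Mean FNR over one meteorological season across the requested years."""
    want = _season_dates(season, years)
    have = pd.DatetimeIndex(stack.time.values)
    idx = have.isin(want)
    if not idx.any():
        raise ValueError(f"stack contains no days of season {season} in years {years}")
    with np.errstate(invalid="ignore"):
        return stack.isel(time=np.flatnonzero(idx)).mean(dim="time", skipna=True).values


def transition_difference(stack: xr.DataArray, season_from: str, season_to: str, years) -> np.ndarray:
    """Intensity of a seasonal transition: mean(season_to) - mean(season_from)."""
    return seasonal_average(stack, season_to, years) - seasonal_average(stack, season_from, years)


def historical_difference(stack_recent: xr.DataArray, stack_baseline: xr.DataArray) -> np.ndarray:
    """Change map: period average of the recent stack minus the baseline's."""
    return period_average(stack_recent) - period_average(stack_baseline)


def transition_change(
    stack_recent: xr.DataArray,
    stack_baseline: xr.DataArray,
    season_from: str,
    season_to: str,
    years_recent,
    years_baseline,
) -> np.ndarray:
    """|transition| recent - |transition| baseline.

    Negative values mean the seasonal contrast weakened (temporal
    homogenization); positive values mean it sharpened (diversification).
    """
    recent = np.abs(transition_difference(stack_recent, season_from, season_to, years_recent))
    base = np.abs(transition_difference(stack_baseline, season_from, season_to, years_baseline))
    return recent - base


# ---------------------------------------------------------------------------
# annual series and the season diameter
# ---------------------------------------------------------------------------

def annual_series(stack: xr.DataArray, year: int) -> np.ndarray:
    """(365, n_lat, n_lon) daily series for one year, Feb 29 folded into
    day-of-year 59 by averaging."""
    dates = pd.DatetimeIndex(stack.time.values)
    in_year = dates.year == year
    if not in_year.any():
        raise ValueError(f"stack has no days in {year}")
    sel = stack.isel(time=np.flatnonzero(in_year))
    d = pd.DatetimeIndex(sel.time.values)
    vals = sel.values
    out = np.full((365, *vals.shape[1:]), np.nan)
    doy = d.dayofyear.values.copy()
    if d.is_leap_year.any() and len(d) and pd.Timestamp(year=year, month=2, day=29) in d:
        feb29 = np.flatnonzero((d.month == 2) & (d.day == 29))[0]
        feb28 = np.flatnonzero((d.month == 2) & (d.day == 28))
        after = doy > 60
        doy[after] -= 1  # shift Mar 1.. back to the non-leap numbering
        mask = np.ones(len(d), bool)
        mask[feb29] = False
        out[doy[mask] - 1] = vals[mask]
        if feb28.size:
            out[58] = 0.5 * (vals[feb28[0]] + vals[feb29])
        else:
            out[58] = vals[feb29]
        return out
    out[doy - 1] = vals
    return out


def season_diameter(series: np.ndarray, mass: float = 0.95) -> tuple[int, int]:
    """Smallest circular window holding ``mass`` of the cumulative FNR.

    Returns (diameter_days, start_index 0-based).  Ties break to the
    earliest start.  All-zero (or all-NaN) series are degenerate and raise.
    """
    s = np.nan_to_num(np.asarray(series, dtype=float), nan=0.0)
    if s.ndim != 1 or s.size != 365:
        raise ValueError("series must be a length-365 vector")
    if (s < 0).any():
        raise ValueError("FNR series must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("degenerate series: zero cumulative FNR (no season)")
    target = mass * total
    cums = np.concatenate([[0.0], np.cumsum(np.concatenate([s, s]))])  # len 731
    # minimal L per start: first index where cums[start+L] - cums[start] >= target
    starts = np.arange(365)
    # searchsorted over the doubled cumulative sum
    idx = np.searchsorted(cums, cums[starts] + target, side="left")
    L = np.minimum(idx - starts, 365)
    d = int(L.min())
    start = int(np.flatnonzero(L == L.min())[0])
    return d, start


def season_midpoint(series: np.ndarray, mass: float = 0.95) -> int:
    """Day-of-year (1..365) splitting the location's cumulative FNR in half.

    Scanning circularly from the start of the season-diameter window, the
    midpoint is the first day at which the accumulated FNR reaches half of
    the year's total mass (the day at which roughly 50% of the cumulative
    FNR lies before and after).  Because the window holds >= ``mass`` of
    the total, the crossing always falls inside it.
    """
    d, start = season_diameter(series, mass)
    s = np.nan_to_num(np.asarray(series, dtype=float), nan=0.0)
    window = np.take(s, (start + np.arange(d)) % 365)
    half = s.sum() / 2.0
    t = int(np.searchsorted(np.cumsum(window), half, side="left"))
    return int((start + t) % 365) + 1


def season_profile_map(stack: xr.DataArray, year: int, mass: float = 0.95) -> SeasonProfile:
    """Per-cell SeasonProfile for one year; degenerate cells get NaN."""
    series = annual_series(stack, year)  # (365, H, W)
    H, W = series.shape[1:]
    diam = np.full((H, W), np.nan)
    mid = np.full((H, W), np.nan)
    total = np.nansum(series, axis=0)
    flat = np.nan_to_num(series, nan=0.0).reshape(365, -1)
    for k in range(flat.shape[1]):
        col = flat[:, k]
        if col.sum() <= 0:
            continue
        d, start = season_diameter(col, mass)
        i, j = divmod(k, W)
        diam[i, j] = d
        window = np.take(col, (start + np.arange(d)) % 365)
        t = int(np.searchsorted(np.cumsum(window), col.sum() / 2.0, side="left"))
        mid[i, j] = (start + t) % 365 + 1
    n_degen = int(np.isnan(diam).sum())
    if n_degen:
        logger.info("season_profile_map: %d degenerate cells (zero FNR mass)", n_degen)
    with np.errstate(invalid="ignore", divide="ignore"):
        seasonality = 1.0 / diam
    return SeasonProfile(diameter=diam, seasonality=seasonality, midpoint=mid,
                         total_mass=total, mass=mass, year=year)


def multi_year_profile(stack: xr.DataArray, years, mass: float = 0.95) -> SeasonProfile:
    """Average of per-year diameters (and midpoints via circular mean) over
    several years; seasonality = 1/mean diameter."""
    profiles = [season_profile_map(stack, int(y), mass) for y in np.atleast_1d(years)]
    diam = np.nanmean(np.stack([p.diameter for p in profiles]), axis=0)
    ang = np.stack([2 * np.pi * (p.midpoint - 1) / 365.0 for p in profiles])
    mid = (np.arctan2(np.nanmean(np.sin(ang), axis=0), np.nanmean(np.cos(ang), axis=0))
           % (2 * np.pi)) / (2 * np.pi) * 365.0 + 1
    total = np.nanmean(np.stack([p.total_mass for p in profiles]), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        seasonality = 1.0 / diam
    return SeasonProfile(diameter=diam, seasonality=seasonality, midpoint=mid,
                         total_mass=total, mass=mass, year=None)


# ---------------------------------------------------------------------------
# visualization exclusion heuristic
# ---------------------------------------------------------------------------

def circular_doy_distance(day: np.ndarray, ref_day: float = 1.0, period: int = 365) -> np.ndarray:
    """Circular distance in days between days-of-year."""
    delta = np.abs(np.asarray(day, dtype=float) - ref_day)
    return np.minimum(delta, period - delta)


def exclusion_mask(
    profile: SeasonProfile,
    window_days: float = 10.0,
    percentiles: tuple[float, float] = (2.0, 98.0),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Mask cells whose season midpoint falls within ``window_days`` of
    Jan 1 (plus degenerate cells) and return the percentile clip range of
    the remaining seasonality values.

    A visualization aid only — never feeds back into any other statistic.
    Percentiles use NumPy's default linear-interpolation order statistics.
    """
    dist = circular_doy_distance(profile.midpoint, 1.0)
    masked = np.isnan(profile.midpoint) | (dist <= window_days)
    remaining = profile.seasonality[~masked]
    remaining = remaining[np.isfinite(remaining)]
    if remaining.size == 0:
        raise ValueError("exclusion mask removed every cell")
    lo, hi = np.percentile(remaining, list(percentiles))
    return masked, (float(lo), float(hi))
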