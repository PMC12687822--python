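"""Person-days at risk: FNR stacks x gridded population.

A cell-day counts toward the burden when its FNR meets the risk threshold
(default 0.5, inclusive); the contribution is the cell's population.  This
is an exposure-risk estimate only — no transmission modeling.  Population
is linearly interpolated between census years, and daily FNR values are
linearly interpolated by day-of-year between modeled years.  Trends over
years are ordinary least squares with a t-based prediction interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .grid_io import GridSpec, PopulationGrid
from .seasonality import annual_series


@dataclass
class BurdenSeries:
    years: list[int]
    person_days: list[float]
    region: str = "global"
    species: str = ""
    threshold: float = 0.5

    def __post_init__(self):
        if list(self.years) != sorted(self.years):
            raise ValueError("years must be ascending")
        if any(v < 0 for v in self.person_days):
            raise ValueError("person-days must be non-negative")


@dataclass
class TrendFit:
    slope: float
    intercept: float
    level: float
    years: list[int]
    fitted: list[float]
    pi_lower: list[float]
    pi_upper: list[float]


def interpolate_population(pop: PopulationGrid, year: float) -> np.ndarray:
    """Per-cell linear interpolation between bracketing census years."""
    years = np.asarray(pop.census_years, dtype=float)
    if not (years[0] <= year <= years[-1]):
        raise ValueError(f"year {year} outside census range {years[0]}..{years[-1]}")
    hi = int(np.searchsorted(years, year, side="left"))
    if years[hi] == year:
        return pop.density[hi].copy()
    lo = hi - 1
    w = (year - years[lo]) / (years[hi] - years[lo])
    return (1 - w) * pop.density[lo] + w * pop.density[hi]


def interpolate_fnr_year(
    stacks_by_year: dict[int, xr.DataArray], target_year: int
) -> np.ndarray:
    """(365, H, W) day-of-year FNR series for ``target_year``.

    Modeled years pass through; intermediate years interpolate per cell and
    day-of-year between the bracketing modeled years, clamped to [0, 1].
    """
    years = sorted(stacks_by_year)
    if target_year in stacks_by_year:
        return annual_series(stacks_by_year[target_year], target_year)
    ys = np.asarray(years, dtype=float)
    if not (ys[0] <= target_year <= ys[-1]):
        raise ValueError(f"target year {target_year} outside modeled range")
    hi = int(np.searchsorted(ys, target_year, side="left"))
    lo = hi - 1
    a = annual_series(stacks_by_year[years[lo]], years[lo])
    b = annual_series(stacks_by_year[years[hi]], years[hi])
    w = (target_year - ys[lo]) / (ys[hi] - ys[lo])
    return np.clip((1 - w) * a + w * b, 0.0, 1.0)


def person_days_at_risk(
    fnr_days: np.ndarray,
    population: np.ndarray,
    threshold: float = 0.5,
    region_mask: np.ndarray | None = None,
) -> float:
    """Sum over region cells and days of population x 1[FNR >= threshold].

    ``fnr_days`` is (n_days, H, W); NaN FNR days never count.
    """
    fnr_days = np.asarray(fnr_days, dtype=float)
    population = np.asarray(population, dtype=float)
    if fnr_days.shape[1:] != population.shape:
        raise ValueError("population raster does not match FNR grid")
    at_risk = np.nan_to_num(fnr_days, nan=-np.inf) >= threshold  # (D, H, W)
    days_at_risk = at_risk.sum(axis=0).astype(float)  # (H, W)
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != population.shape:
            raise ValueError("region mask shape mismatch")
        days_at_risk = np.where(region_mask, days_at_risk, 0.0)
    return float(np.sum(days_at_risk * population))


def box_region_mask(grid: GridSpec, lat_range, lon_range) -> np.ndarray:
    """Boolean mask of cells whose centers fall in a lat/lon box (inclusive)."""
    lat = grid.lat_centers[:, None]
    lon = grid.lon_centers[None, :]
    return (
        (lat >= lat_range[0]) & (lat <= lat_range[1])
        & (lon >= lon_range[0]) & (lon <= lon_range[1])
    ) * np.ones((grid.n_lat, grid.n_lon), dtype=bool)


def burden_series(
    stacks_by_year: dict[int, xr.DataArray],
    pop: PopulationGrid,
    years,
    threshold: float = 0.5,
    region_mask: np.ndarray | None = None,
    region: str = "global",
    species: str = "",
) -> BurdenSeries:
    """Person-days at risk per year, interpolating both FNR and population."""
    vals = []
    for y in years:
        fnr = interpolate_fnr_year(stacks_by_year, int(y))
        p = interpolate_population(pop, float(y))
        vals.append(person_days_at_risk(fnr, p, threshold, region_mask))
    return BurdenSeries(years=list(years), person_days=vals, region=region,
                        species=species, threshold=threshold)


def fit_trend(series: BurdenSeries, level: float = 0.90) -> TrendFit:
    """OLS person-days ~ year with a t-based prediction interval at ``level``."""
    years = np.asarray(series.years, dtype=float)
    y = np.asarray(series.person_days, dtype=float)
    X = sm.add_constant(years)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=1.0 - level)
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        level=level,
        years=list(series.years),
        fitted=pred["mean"].tolist(),
        pi_lower=pred["obs_ci_lower"].tolist(),
        pi_upper=pred["obs_ci_upper"].tolist(),
    )
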