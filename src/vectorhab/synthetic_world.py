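"""A fully synthetic planet with a known habitability law.

The generator emulates the structural features of the real inputs that the
pipeline must detect — an equator-to-pole temperature gradient, a seasonal
cycle in antiphase across hemispheres, a wet season, rectangular
continents, effort-weighted presence records drawn from a logistic
habitability law on 30-day trailing climate — without any claim to
climatological realism.  Because the habitability law is known in closed
form, parameter-recovery and calibration-uniformity experiments can be run
entirely offline.

All stochastic steps take explicit seeds; every generated artifact can
embed its :class:`WorldConfig` for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import special

from .grid_io import OBS_COLUMNS, ClimateCube, GridSpec, LandMask, PopulationGrid


@dataclass
class WorldConfig:
    """Synthetic-world parameters (units in comments).

    The defaults describe a small planet: a 40 x 80 grid spanning
    latitudes +-58.5 deg, two simulated years, two rectangular continents,
    and a habitability law peaking at 24 degC with a wet-season bonus.
    """

    # grid / time
    n_lat: int = 40
    n_lon: int = 80
    lat_span: float = 117.0        # degrees, centered on the equator
    years: int = 2
    start_date: str = "2023-01-01"
    seed: int = 1

    # climate law
    base_temp: float = 28.0        # degC at the equator, annual mean
    lat_gradient: float = 33.0     # degC decrease from equator to |lat|=90
    seasonal_amplitude: float = 10.0  # degC at |lat|=90, antiphase by hemisphere
    peak_doy_north: int = 196      # northern-summer temperature peak (mid July)
    diurnal_range: float = 8.0     # degC, tmax - tmin
    dew_depression_base: float = 4.0   # degC below tmean at the equator
    dew_depression_polar: float = 4.0  # extra depression at |lat|=90
    precip_base: float = 0.12      # mm/hr annual-mean average hourly rate
    wet_amplitude: float = 0.8     # relative wet-season swing
    wet_peak_doy_north: int = 196  # wet season peaks with local summer
    wind_mean: float = 3.0         # m/s
    # daily noise: a spatially coherent anomaly shared by all cells on a day
    # (weather systems are large relative to this grid) plus a small
    # cell-local component
    noise_sd_temp: float = 1.2     # degC, common daily anomaly
    noise_sd_temp_local: float = 0.2   # degC, per cell-day
    noise_sd_precip: float = 0.02  # mm/hr, common daily anomaly
    noise_sd_precip_local: float = 0.01  # mm/hr, per cell-day
    noise_sd_wind: float = 0.8     # m/s, common daily anomaly
    noise_sd_wind_local: float = 0.2     # m/s, per cell-day

    # continents: (row0, row1, col0, col1) half-open cell ranges
    continents: tuple = ((4, 36, 8, 30), (8, 32, 45, 72))

    # habitability law on 30-day trailing means; a selective thermal niche
    # (roughly +-3 degC around the optimum) so presences concentrate in a
    # warm band the classifier must find
    hab_beta0: float = 1.5         # logit at T30 = T_opt, P30 = p_ref
    hab_beta_T: float = -0.25      # per degC^2, quadratic falloff
    hab_T_opt: float = 26.0        # degC
    hab_beta_P: float = 0.3        # per (mm/day)
    hab_p_ref: float = 3.0         # mm/day
    trailing_days: int = 30

    # observation process
    target_presences: int = 500    # expected count when effort_scale is None
    effort_scale: float | None = None  # absolute per-cell-day rate multiplier
    effort_hotspots: tuple = ()    # ((row, col, sigma_cells, gain), ...)
    obs_jitter: bool = True

    # population
    pop_census_years: tuple = (2023, 2024)
    pop_total: float = 1e6         # persons at the first census year
    pop_growth: float = 1.1        # multiplier between census years
    pop_hotspots: tuple = ((20, 20, 4.0), (18, 58, 6.0))  # (row, col, sigma)

    def __post_init__(self):
        if self.n_lat < 4 or self.n_lon < 4:
            raise ValueError("grid must be at least 4x4")
        if self.seasonal_amplitude < 0 or self.noise_sd_temp < 0:
            raise ValueError("amplitudes and noise sds must be non-negative")

    @property
    def grid(self) -> GridSpec:
        dlat = self.lat_span / self.n_lat
        dlon = 360.0 / self.n_lon
        return GridSpec(
            lat_min=-self.lat_span / 2 + dlat / 2,
            lon_min=-180.0 + dlon / 2,
            n_lat=self.n_lat,
            n_lon=self.n_lon,
            cell_size_lat=dlat,
            cell_size_lon=dlon,
        )

    @property
    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start_date)
        return pd.date_range(start, periods=self.years * 365, freq="D")

    def to_dict(self) -> dict:
        return asdict(self)


def _seasonal_factor(lat: np.ndarray, doy: np.ndarray, peak_doy: int) -> np.ndarray:
    """(lat/90)-scaled annual cosine peaking at ``peak_doy`` in the north;
    the sign of lat flips the phase by exactly half a year."""
    phase = 2.0 * np.pi * (doy[:, None] - peak_doy) / 365.0
    return (lat[None, :] / 90.0) * np.cos(phase)


def generate_climate(config: WorldConfig) -> tuple[ClimateCube, LandMask]:
    """Daily raw climate cube plus the continents land mask."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    dates = config.dates
    lat = grid.lat_centers
    doy = dates.dayofyear.to_numpy().astype(float)
    T, H, W = len(dates), grid.n_lat, grid.n_lon

    def daily_noise(sd_common, sd_local):
        out = np.zeros((T, H, W))
        if sd_common > 0:
            out += rng.normal(0, sd_common, (T, 1, 1))
        if sd_local > 0:
            out += rng.normal(0, sd_local, (T, H, W))
        return out

    season_T = config.seasonal_amplitude * _seasonal_factor(lat, doy, config.peak_doy_north)
    tmean_base = (config.base_temp - config.lat_gradient * np.abs(lat) / 90.0)[None, :] + season_T
    tmean = tmean_base[:, :, None] + daily_noise(config.noise_sd_temp, config.noise_sd_temp_local)

    half_range = config.diurnal_range / 2.0
    tmax = tmean + half_range + daily_noise(0.2, 0.1)
    tmin = tmean - half_range + daily_noise(0.2, 0.1)
    np.minimum(tmin, tmax, out=tmin)

    depression = (config.dew_depression_base
                  + config.dew_depression_polar * np.abs(lat) / 90.0)[None, :, None]
    tdew = tmean - depression + daily_noise(0.3, 0.1)
    np.minimum(tdew, tmean, out=tdew)

    season_P = config.wet_amplitude * _seasonal_factor(lat, doy, config.wet_peak_doy_north)
    precip = config.precip_base * (1.0 + season_P)[:, :, None] \
        + daily_noise(config.noise_sd_precip, config.noise_sd_precip_local)
    np.clip(precip, 0.0, None, out=precip)

    u = config.wind_mean + daily_noise(config.noise_sd_wind, config.noise_sd_wind_local)
    v = daily_noise(config.noise_sd_wind, config.noise_sd_wind_local)

    ds = xr.Dataset(
        {
            "tmean": (("time", "lat", "lon"), tmean),
            "tmax": (("time", "lat", "lon"), tmax),
            "tmin": (("time", "lat", "lon"), tmin),
            "tdew": (("time", "lat", "lon"), tdew),
            "precip_hourly": (("time", "lat", "lon"), precip),
            "uwind": (("time", "lat", "lon"), u),
            "vwind": (("time", "lat", "lon"), v),
        },
        coords={"time": dates, "lat": lat, "lon": grid.lon_centers},
    )
    for v_ in ("tmean", "tmax", "tmin", "tdew"):
        ds[v_].attrs["units"] = "degC"

    is_land = np.zeros((H, W), dtype=bool)
    for r0, r1, c0, c1 in config.continents:
        is_land[r0:r1, c0:c1] = True
    return ClimateCube(ds), LandMask(grid=grid, is_land=is_land)


def true_habitability(cube: ClimateCube, config: WorldConfig) -> xr.DataArray:
    """Ground-truth habitability per (cell, date), for dates with a full
    trailing window.

    logit = beta0 + beta_T * (T30 - T_opt)^2 + beta_P * (P30 - p_ref),
    where T30/P30 are the means of daily mean temperature and total daily
    precipitation over the ``trailing_days`` days strictly before the date.
    Deterministic given the climate cube.
    """
    k = config.trailing_days
    tmean = cube.data["tmean"].values
    ptot = 24.0 * np.clip(cube.data["precip_hourly"].values, 0.0, None)
    # trailing mean over the k days strictly before index t -> valid from t=k
    cs_t = np.cumsum(tmean, axis=0)
    cs_p = np.cumsum(ptot, axis=0)
    t30 = (cs_t[k - 1 : -1] - np.concatenate([np.zeros((1, *tmean.shape[1:])), cs_t[:-k - 1]])) / k
    p30 = (cs_p[k - 1 : -1] - np.concatenate([np.zeros((1, *ptot.shape[1:])), cs_p[:-k - 1]])) / k
    logit = (config.hab_beta0
             + config.hab_beta_T * (t30 - config.hab_T_opt) ** 2
             + config.hab_beta_P * (p30 - config.hab_p_ref))
    prob = special.expit(logit)
    dates = cube.dates[k:]
    return xr.DataArray(
        prob,
        dims=("time", "lat", "lon"),
        coords={"time": dates, "lat": cube.data.lat, "lon": cube.data.lon},
        name="habitability",
    )


def true_habitability_at(cell: tuple[int, int], date, cube: ClimateCube,
                         config: WorldConfig) -> float:
    """Scalar habitability at one (cell, date)."""
    hab = true_habitability(cube, config)
    return float(hab.sel(time=pd.Timestamp(date)).values[cell[0], cell[1]])


def _effort_field(config: WorldConfig, mask: LandMask) -> np.ndarray:
    """Relative observation-effort raster (>= 0, zero off land)."""
    effort = np.ones(mask.grid.shape, dtype=float)
    rows = np.arange(mask.grid.n_lat)[:, None]
    cols = np.arange(mask.grid.n_lon)[None, :]
    for r, c, sigma, gain in config.effort_hotspots:
        effort += gain * np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sigma**2))
    effort[~mask.is_land] = 0.0
    return effort


def sample_observations(
    config: WorldConfig,
    cube: ClimateCube,
    mask: LandMask,
    window: tuple | None = None,
    species: str = "Synthetica exemplaris",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Presence records from a thinned point process.

    P(record at cell, date) = effort_scale * effort(cell) * hab(cell, date),
    capped at 1.  When ``effort_scale`` is None it is set so the expected
    record count equals ``target_presences`` (an explicit float keeps the
    count proportional to effort, which the doubling property uses).  The
    default window is every date with a full trailing-climate window,
    shifted to leave at least one year of history for long sequences.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    hab = true_habitability(cube, config)
    dates = pd.DatetimeIndex(hab.time.values)
    if window is None:
        start = cube.dates[0] + pd.Timedelta(days=365) if config.years >= 2 else dates[0]
        window = (max(dates[0], start), dates[-1])
    sel = (dates >= pd.Timestamp(window[0])) & (dates <= pd.Timestamp(window[1]))
    hab_w = hab.values[sel]  # (D, H, W)
    dates_w = dates[sel]

    effort = _effort_field(config, mask)
    rate = effort[None, :, :] * hab_w
    scale = config.effort_scale
    if scale is None:
        total = rate.sum()
        if total <= 0:
            return pd.DataFrame(columns=OBS_COLUMNS)
        scale = config.target_presences / total
    p = np.clip(scale * rate, 0.0, 1.0)
    hits = rng.random(p.shape) < p
    d_idx, rows, cols = np.nonzero(hits)
    if d_idx.size == 0:
        return pd.DataFrame(columns=OBS_COLUMNS)

    grid = mask.grid
    lat = grid.lat_centers[rows]
    lon = grid.lon_centers[cols]
    if config.obs_jitter:
        lat = lat + rng.uniform(-0.49, 0.49, lat.size) * grid.cell_size_lat
        lon = lon + rng.uniform(-0.49, 0.49, lon.size) * grid.cell_size_lon
    return pd.DataFrame(
        {
            "species": species,
            "date": dates_w[d_idx],
            "lat": lat,
            "lon": lon,
            "label": 1,
            "cell_row": rows,
            "cell_col": cols,
            "provenance": "presence",
        },
        columns=OBS_COLUMNS,
    )


def generate_population(config: WorldConfig) -> PopulationGrid:
    """Smooth hotspot population at the configured census years.

    Census-year totals are ``pop_total * pop_growth**k`` exactly.
    """
    grid = config.grid
    rows = np.arange(grid.n_lat)[:, None]
    cols = np.arange(grid.n_lon)[None, :]
    base = np.zeros(grid.shape, dtype=float)
    for r, c, sigma in config.pop_hotspots:
        base += np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sigma**2))
    base /= base.sum()
    rasters = [config.pop_total * config.pop_growth**k * base
               for k in range(len(config.pop_census_years))]
    return PopulationGrid(grid=grid, census_years=list(config.pop_census_years),
                          density=np.stack(rasters))


def generate_world(config: WorldConfig | None = None):
    """Convenience: (cube, mask, observations, population, habitability)."""
    config = config or WorldConfig()
    cube, mask = generate_climate(config)
    obs = sample_observations(config, cube, mask)
    pop = generate_population(config)
    hab = true_habitability(cube, config)
    return cube, mask, obs, pop, hab
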