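"""Derived daily climate covariates and flattened feature sequences.

Five covariates are computed per day and cell from the raw reanalysis-style
variables:

* ``trange`` — diurnal temperature range, ``tmax - tmin`` (degC, clamped >= 0)
* ``tmean`` — central (daily mean) 2-m air temperature (degC)
* ``rh``    — relative humidity (%) from the August-Roche-Magnus ratio of
  saturation vapour pressures at the dew point and at the mean temperature
* ``ptot``  — total daily precipitation, 24 x average hourly rate (mm/day)
* ``wspd``  — wind magnitude from the u/v components (m/s)

Note on naming: some descriptions of this covariate set call the central
temperature the *median* air temperature; the daily *mean* 2-m temperature
is what reanalysis products provide daily and what the humidity formula
consumes, so that is what ``tmean`` holds.

A model input is a *flattened sequence*: for an observation at (cell, date)
the ``seq_len`` days strictly before the date are stacked day-major (oldest
day first), each contributing the five covariates in the fixed order
:data:`DERIVED_VARS`.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.preprocessing import StandardScaler

from .grid_io import ClimateCube

logger = logging.getLogger(__name__)

#: fixed variable order of the flattened sequence (recorded in checkpoints).
DERIVED_VARS = ("trange", "tmean", "rh", "ptot", "wspd")

_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # degC


class InsufficientHistoryError(ValueError):
    """A feature sequence was requested with too little climate history."""


def relative_humidity(t_dew, t_mean):
    """Relative humidity (%) via the August-Roche-Magnus equation.

    RH = 100 * exp(17.625*Td / (243.04+Td)) / exp(17.625*Tm / (243.04+Tm))

    Values above 100% are possible (supersaturation in reanalysis data) and
    are deliberately not clipped; the downstream z-score normalization
    absorbs the scale.
    """
    t_dew = np.asarray(t_dew, dtype=float)
    t_mean = np.asarray(t_mean, dtype=float)
    if np.any(t_dew <= -_MAGNUS_B) or np.any(t_mean <= -_MAGNUS_B):
        raise ValueError(f"temperatures must exceed {-_MAGNUS_B} degC")
    rh = 100.0 * np.exp(_MAGNUS_A * t_dew / (_MAGNUS_B + t_dew)) / np.exp(
        _MAGNUS_A * t_mean / (_MAGNUS_B + t_mean)
    )
    return rh if rh.ndim else float(rh)


def daily_precip_total(avg_hourly):
    """Total daily precipitation (mm/day) = 24 x average hourly rate (mm/hr)."""
    avg_hourly = np.asarray(avg_hourly, dtype=float)
    if np.any(avg_hourly < 0):
        raise ValueError("average hourly precipitation must be non-negative")
    out = 24.0 * avg_hourly
    return out if out.ndim else float(out)


def wind_magnitude(u, v):
    """Wind speed magnitude sqrt(u^2 + v^2) (m/s)."""
    out = np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
    return out if out.ndim else float(out)


def temperature_range(t_max, t_min):
    """Diurnal range t_max - t_min (degC); inversions clamp to 0 with a warning."""
    diff = np.asarray(t_max, dtype=float) - np.asarray(t_min, dtype=float)
    n_bad = int(np.sum(diff < 0))
    if n_bad:
        warnings.warn(f"temperature_range: {n_bad} t_max < t_min values clamped to 0")
        diff = np.clip(diff, 0.0, None)
    return diff if diff.ndim else float(diff)


def derive_all(cube: ClimateCube) -> xr.Dataset:
    """Compute the five derived daily covariates for every cell and day.

    Negative reanalysis precipitation artifacts are clamped to zero (counted
    in the log); the output carries the same grid and date index as the
    input.
    """
    ds = cube.data
    precip = ds["precip_hourly"].values
    n_neg = int(np.sum(precip < 0))
    if n_neg:
        logger.warning("derive_all: clamped %d negative precipitation values", n_neg)
        precip = np.clip(precip, 0.0, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamp warning already logged upstream
        trange = temperature_range(ds["tmax"].values, ds["tmin"].values)
    out = xr.Dataset(
        {
            "trange": (("time", "lat", "lon"), np.atleast_3d(trange)),
            "tmean": (("time", "lat", "lon"), ds["tmean"].values),
            "rh": (("time", "lat", "lon"), relative_humidity(ds["tdew"].values, ds["tmean"].values)),
            "ptot": (("time", "lat", "lon"), daily_precip_total(precip)),
            "wspd": (("time", "lat", "lon"), wind_magnitude(ds["uwind"].values, ds["vwind"].values)),
        },
        coords={"time": ds.time, "lat": ds.lat, "lon": ds.lon},
    )
    return out


def _derived_array(derived: xr.Dataset, variables=DERIVED_VARS) -> np.ndarray:
    """Stack a derived cube to shape (n_days, n_vars, n_lat, n_lon)."""
    return np.stack([derived[v].values for v in variables], axis=1)


def assemble_sequence(
    derived: xr.Dataset,
    cell: tuple[int, int],
    date,
    seq_len: int,
    variables=DERIVED_VARS,
) -> np.ndarray:
    """Flattened feature vector for one (cell, date).

    Takes the ``seq_len`` days strictly before ``date`` (the observation day
    itself is excluded), oldest day first, each day contributing
    ``variables`` in order; length ``seq_len * len(variables)``.
    """
    date = pd.Timestamp(date).normalize()
    dates = pd.DatetimeIndex(derived.time.values)
    start = date - pd.Timedelta(days=seq_len)
    if start < dates[0] or date - pd.Timedelta(days=1) > dates[-1]:
        raise InsufficientHistoryError(
            f"sequence for {date.date()} needs days from {start.date()}; "
            f"cube covers {dates[0].date()}..{dates[-1].date()}"
        )
    i0 = dates.get_loc(start)
    i, j = cell
    window = np.stack(
        [derived[v].values[i0 : i0 + seq_len, i, j] for v in variables], axis=1
    )  # (seq_len, n_vars), day-major
    return window.reshape(-1).astype(np.float64)


def assemble_matrix(
    derived: xr.Dataset,
    cells: np.ndarray,
    dates,
    seq_len: int,
    variables=DERIVED_VARS,
) -> np.ndarray:
    """Vectorized :func:`assemble_sequence` over rows of (cell, date).

    ``cells`` is (n, 2) int rows/cols; ``dates`` a length-n datetime sequence.
    """
    all_dates = pd.DatetimeIndex(derived.time.values)
    dates = pd.DatetimeIndex(dates).normalize()
    arr = _derived_array(derived, variables)  # (T, V, H, W)
    t0 = all_dates[0]
    day_idx = ((dates - t0) // pd.Timedelta(days=1)).to_numpy()
    starts = day_idx - seq_len
    if (starts < 0).any() or (day_idx > len(all_dates)).any():
        bad = dates[(starts < 0) | (day_idx > len(all_dates))][0]
        raise InsufficientHistoryError(f"insufficient climate history for {bad.date()}")
    offsets = np.arange(seq_len)
    ti = starts[:, None] + offsets[None, :]  # (n, seq_len)
    rows = np.asarray(cells)[:, 0][:, None]
    cols = np.asarray(cells)[:, 1][:, None]
    window = arr[ti, :, rows, cols]  # (n, seq_len, V)
    return window.reshape(len(dates), -1).astype(np.float64)


def assemble_map_matrix(derived: xr.Dataset, date, seq_len: int, variables=DERIVED_VARS) -> np.ndarray:
    """Feature matrix for every grid cell at one prediction date.

    Returns (n_lat * n_lon, seq_len * n_vars), row-major over cells.
    """
    date = pd.Timestamp(date).normalize()
    all_dates = pd.DatetimeIndex(derived.time.values)
    start = date - pd.Timedelta(days=seq_len)
    if start < all_dates[0] or date - pd.Timedelta(days=1) > all_dates[-1]:
        raise InsufficientHistoryError(f"insufficient climate history for {date.date()}")
    i0 = all_dates.get_loc(start)
    arr = _derived_array(derived, variables)[i0 : i0 + seq_len]  # (seq_len, V, H, W)
    n_cells = arr.shape[2] * arr.shape[3]
    # -> (H*W, seq_len*V), day-major per cell
    return (
        arr.reshape(seq_len * len(variables), n_cells).T.astype(np.float64).copy()
    )


class SequenceScaler(StandardScaler):
    """Per-feature z-score scaler for flattened sequences.

    Thin subclass of :class:`sklearn.preprocessing.StandardScaler`: fitted on
    the training split only and frozen into the model checkpoint so the same
    statistics are reused at inference.  Constant features scale by 1 (the
    sklearn convention), which the contract here requires.
    """

    def fit(self, X, y=None, sample_weight=None):
        out = super().fit(X, y, sample_weight=sample_weight)
        n_const = int(np.sum(np.asarray(self.var_) == 0))
        if n_const:
            warnings.warn(f"SequenceScaler: {n_const} constant features scaled by 1")
        return out


def fit_scaler(X: np.ndarray) -> SequenceScaler:
    return SequenceScaler().fit(X)


def apply_scaler(scaler: SequenceScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(np.atleast_2d(X))
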