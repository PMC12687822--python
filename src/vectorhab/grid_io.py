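"""Gridded climate, land-mask, population and observation I/O.

Everything downstream works on a single regular lat/lon grid described by
:class:`GridSpec`.  The conventions here mirror ERA5-style reanalysis
products: cell-center registration, 0.25 degree default spacing, longitudes
normalized to [-180, 180).  Climate cubes are thin wrappers around
:class:`xarray.Dataset` (dims ``time, lat, lon``); observation tables are
pandas DataFrames with a fixed schema.

NetCDF is read/written through xarray's scipy backend (NetCDF3, classic
model); GeoTIFF through tifffile with GeoTIFF ModelPixelScale /
ModelTiepoint tags so georeferencing round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: raw climate variables expected in a ClimateCube, with units.
RAW_VARS = {
    "tmean": "degC",   # mean 2-m air temperature
    "tmax": "degC",    # max 2-m air temperature
    "tmin": "degC",    # min 2-m air temperature
    "tdew": "degC",    # dew point temperature
    "precip_hourly": "mm/hr",  # average hourly precipitation
    "uwind": "m/s",
    "vwind": "m/s",
}

#: optional extras tolerated in a cube (accessed in reanalysis pulls but
#: never entering the model).
OPTIONAL_VARS = ("surface_pressure",)

_KELVIN_UNITS = {"k", "kelvin", "degk", "deg_k"}
_ZERO_C_IN_K = 273.15


class GridError(ValueError):
    """Raised for grid-geometry violations."""


def normalize_lon(lon):
    """Normalize longitudes to [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid, cell-center registered.

    ``lat_min``/``lon_min`` are the *centers* of the south-west corner cell.
    """

    lat_min: float
    lon_min: float
    n_lat: int
    n_lon: int
    cell_size_lat: float = 0.25
    cell_size_lon: float = 0.25

    def __post_init__(self):
        if self.cell_size_lat <= 0 or self.cell_size_lon <= 0:
            raise GridError("cell sizes must be positive")
        if self.n_lat < 1 or self.n_lon < 1:
            raise GridError("grid must have at least one cell per axis")
        if not (-90.0 < self.lat_min and self.lat_max < 90.0):
            raise GridError("cell centers must lie strictly within [-90, 90]")
        if not (-180.0 <= self.lon_min and self.lon_max < 180.0):
            raise GridError("cell-center longitudes must lie in [-180, 180)")

    @property
    def lat_max(self) -> float:
        return self.lat_min + (self.n_lat - 1) * self.cell_size_lat

    @property
    def lon_max(self) -> float:
        return self.lon_min + (self.n_lon - 1) * self.cell_size_lon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_size_lat * np.arange(self.n_lat)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size_lon * np.arange(self.n_lon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def contains(self, lat: float, lon: float) -> bool:
        """Point within the grid's outer cell edges."""
        h_lat = self.cell_size_lat / 2.0
        h_lon = self.cell_size_lon / 2.0
        return (
            self.lat_min - h_lat <= lat <= self.lat_max + h_lat
            and self.lon_min - h_lon <= lon <= self.lon_max + h_lon
        )

    def snap_to_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest cell (row, col) by plain lat/lon Euclidean distance.

        Ties break to the lowest row index, then the lowest column index,
        which `round half down` achieves on a regular grid.
        """
        lon = float(normalize_lon(lon))
        if not self.contains(lat, lon):
            raise GridError(f"point (lat={lat}, lon={lon}) outside grid extent")
        # halfway points round down to the lower index
        i = int(np.ceil((lat - self.lat_min) / self.cell_size_lat - 0.5))
        j = int(np.ceil((lon - self.lon_min) / self.cell_size_lon - 0.5))
        i = min(max(i, 0), self.n_lat - 1)
        j = min(max(j, 0), self.n_lon - 1)
        return i, j

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.lat_min + i * self.cell_size_lat,
            self.lon_min + j * self.cell_size_lon,
        )

    def to_dict(self) -> dict:
        return {
            "lat_min": self.lat_min,
            "lon_min": self.lon_min,
            "n_lat": self.n_lat,
            "n_lon": self.n_lon,
            "cell_size_lat": self.cell_size_lat,
            "cell_size_lon": self.cell_size_lon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)

    @classmethod
    def from_coords(cls, lat: np.ndarray, lon: np.ndarray) -> "GridSpec":
        """Recover a GridSpec from monotone coordinate-center vectors."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        dlat = np.diff(lat)
        dlon = np.diff(lon)
        if lat.size > 1 and not np.allclose(dlat, dlat[0]):
            raise GridError("latitude centers are not evenly spaced")
        if lon.size > 1 and not np.allclose(dlon, dlon[0]):
            raise GridError("longitude centers are not evenly spaced")
        return cls(
            lat_min=float(lat[0]),
            lon_min=float(lon[0]),
            n_lat=lat.size,
            n_lon=lon.size,
            cell_size_lat=float(dlat[0]) if lat.size > 1 else 0.25,
            cell_size_lon=float(dlon[0]) if lon.size > 1 else 0.25,
        )


def snap_to_cell(lat: float, lon: float, grid: GridSpec) -> tuple[int, int]:
    """Functional wrapper over :meth:`GridSpec.snap_to_cell`."""
    return grid.snap_to_cell(lat, lon)


# ---------------------------------------------------------------------------
# climate cube
# ---------------------------------------------------------------------------

@dataclass
class ClimateCube:
    """Daily multi-variable raster stack on a regular lat/lon grid."""

    data: xr.Dataset

    def __post_init__(self):
        missing = [v for v in RAW_VARS if v not in self.data.data_vars]
        if missing:
            raise ValueError(f"climate cube missing variables: {missing}")
        _check_contiguous_dates(self.dates)
        for v in self.data.data_vars:
            if tuple(self.data[v].dims) != ("time", "lat", "lon"):
                raise ValueError(f"variable {v!r} must have dims (time, lat, lon)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_coords(self.data.lat.values, self.data.lon.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.time.values).normalize()

    def var(self, name: str) -> np.ndarray:
        return self.data[name].values

    def subset_cells(self, lat_slice: slice, lon_slice: slice) -> "ClimateCube":
        return ClimateCube(self.data.isel(lat=lat_slice, lon=lon_slice))


@dataclass
class LandMask:
    grid: GridSpec
    is_land: np.ndarray

    def __post_init__(self):
        self.is_land = np.asarray(self.is_land, dtype=bool)
        if self.is_land.shape != self.grid.shape:
            raise ValueError("land mask shape does not match grid")
        if not self.is_land.any():
            raise ValueError("land mask has no land cells")

    @property
    def land_indices(self) -> np.ndarray:
        """(n_land, 2) array of (row, col) land cells."""
        return np.argwhere(self.is_land)


@dataclass
class PopulationGrid:
    """Per-census-year population rasters on the model grid (persons per cell)."""

    grid: GridSpec
    census_years: list[int]
    density: np.ndarray  # (n_years, n_lat, n_lon), persons per cell

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if len(self.census_years) < 2:
            raise ValueError("need at least two census years for interpolation")
        if sorted(self.census_years) != list(self.census_years):
            raise ValueError("census years must be ascending")
        if self.density.shape != (len(self.census_years), *self.grid.shape):
            raise ValueError("population raster shape mismatch")
        if (self.density < 0).any():
            raise ValueError("population densities must be non-negative")


def _check_contiguous_dates(dates: pd.DatetimeIndex) -> None:
    if len(dates) == 0:
        raise ValueError("empty date index")
    expected = pd.date_range(dates[0], dates[-1], freq="D")
    if len(expected) != len(dates) or (expected != dates).any():
        missing = expected.difference(dates)
        raise ValueError(
            "date index has gaps; missing dates: "
            + ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
        )


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

OBS_COLUMNS = ["species", "date", "lat", "lon", "label", "cell_row", "cell_col", "provenance"]


@dataclass
class ObservationReport:
    n_read: int = 0
    n_kept: int = 0
    skipped: dict = field(default_factory=dict)

    def skip(self, reason: str, n: int = 1) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + n


def read_observations(
    path,
    grid: GridSpec,
    *,
    dates_available: pd.DatetimeIndex | None = None,
    seq_len: int | None = None,
) -> tuple[pd.DataFrame, ObservationReport]:
    """Parse a presence CSV (``species,date,latitude,longitude``) and snap to cells.

    Malformed rows (bad coordinates, unparseable dates, points off-grid) are
    skipped and counted in the report.  When ``dates_available`` and
    ``seq_len`` are given, rows whose date leaves fewer than ``seq_len`` full
    days of climate history are skipped with reason ``insufficient history``.
    """
    raw = pd.read_csv(path)
    required = {"species", "date", "latitude", "longitude"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"observation CSV missing required columns: {sorted(missing)}")
    if len(raw) == 0:
        raise ValueError("observation CSV is empty")

    report = ObservationReport(n_read=len(raw))
    dates = pd.to_datetime(raw["date"], errors="coerce").dt.normalize()
    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    lon = pd.to_numeric(raw["longitude"], errors="coerce")

    rows = []
    for k in range(len(raw)):
        if pd.isna(dates.iloc[k]):
            report.skip("unparseable date")
            continue
        la, lo = lat.iloc[k], lon.iloc[k]
        if pd.isna(la) or pd.isna(lo) or not (-90.0 <= la <= 90.0):
            report.skip("invalid coordinates")
            continue
        lo = float(normalize_lon(lo))
        if not grid.contains(la, lo):
            report.skip("outside grid extent")
            continue
        if dates_available is not None and seq_len is not None:
            d = dates.iloc[k]
            if d < dates_available[0] + pd.Timedelta(days=seq_len):
                report.skip("insufficient history")
                continue
            if d > dates_available[-1] + pd.Timedelta(days=1):
                report.skip("after climate record")
                continue
        i, j = grid.snap_to_cell(float(la), lo)
        rows.append((str(raw["species"].iloc[k]), dates.iloc[k], float(la), lo, 1, i, j, "presence"))

    if report.skipped:
        logger.warning("read_observations skipped rows: %s", report.skipped)
    report.n_kept = len(rows)
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return df, report


# ---------------------------------------------------------------------------
# climate readers / writers
# ---------------------------------------------------------------------------

def _maybe_kelvin_to_celsius(da: xr.DataArray) -> xr.DataArray:
    units = str(da.attrs.get("units", "")).strip().lower()
    if units in _KELVIN_UNITS:
        out = da - _ZERO_C_IN_K
        out.attrs = dict(da.attrs, units="degC")
        return out
    return da


def read_climate_netcdf(paths, var_names: dict[str, str] | None = None) -> ClimateCube:
    """Read one or more NetCDF files into a contiguous-date :class:`ClimateCube`.

    ``var_names`` maps the cube's canonical names (keys of :data:`RAW_VARS`)
    to the variable names used in the files; identity by default.  Kelvin
    temperatures are converted to Celsius when the units attribute says so.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    var_names = var_names or {}
    parts = [xr.open_dataset(p, engine="scipy", decode_timedelta=False) for p in paths]
    ds = xr.concat(parts, dim="time") if len(parts) > 1 else parts[0]
    ds = ds.sortby("time")
    rename = {src: canon for canon, src in var_names.items() if src in ds.data_vars}
    ds = ds.rename(rename)
    missing = [v for v in RAW_VARS if v not in ds.data_vars]
    if missing:
        raise ValueError(f"NetCDF input missing variables: {missing}")
    out = {}
    for v in list(RAW_VARS) + [x for x in OPTIONAL_VARS if x in ds.data_vars]:
        out[v] = _maybe_kelvin_to_celsius(ds[v]) if RAW_VARS.get(v) == "degC" else ds[v]
    cube = ClimateCube(xr.Dataset(out, coords={"time": ds.time, "lat": ds.lat, "lon": ds.lon}))
    return cube


def read_climate_geotiff_dir(root, grid: GridSpec | None = None) -> ClimateCube:
    """Read a ``<var>/<YYYY-MM-DD>.tif`` directory tree into a ClimateCube.

    Every canonical variable directory must contain the same contiguous set
    of dates; a gap is a hard error naming the missing dates.
    """
    root = Path(root)
    data = {}
    ref_dates = None
    for v in RAW_VARS:
        vdir = root / v
        if not vdir.is_dir():
            raise ValueError(f"missing variable directory: {vdir}")
        files = sorted(vdir.glob("*.tif"))
        dates = pd.DatetimeIndex([pd.Timestamp(f.stem) for f in files])
        _check_contiguous_dates(dates)
        if ref_dates is None:
            ref_dates = dates
        elif not dates.equals(ref_dates):
            raise ValueError(f"variable {v} date index differs from {list(RAW_VARS)[0]}")
        rasters, g = [], None
        for f in files:
            arr, gs = read_geotiff(f)
            g = g or gs
            rasters.append(arr)
        grid = grid or g
        data[v] = np.stack(rasters)
    ds = xr.Dataset(
        {v: (("time", "lat", "lon"), a) for v, a in data.items()},
        coords={"time": ref_dates, "lat": grid.lat_centers, "lon": grid.lon_centers},
    )
    return ClimateCube(ds)


def read_climate(paths, grid: GridSpec | None = None, var_names=None) -> ClimateCube:
    """Dispatch on input kind: NetCDF file(s) or a GeoTIFF directory tree."""
    first = paths[0] if isinstance(paths, (list, tuple)) else paths
    if Path(first).is_dir():
        return read_climate_geotiff_dir(first, grid)
    return read_climate_netcdf(paths, var_names)


def write_climate_netcdf(cube: ClimateCube | xr.Dataset, path) -> None:
    ds = cube.data if isinstance(cube, ClimateCube) else cube
    ds = ds.copy()
    # scipy backend cannot encode datetime64 attrs cleanly; ensure plain coords
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# GeoTIFF (tifffile + GeoTIFF tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def write_geotiff(arr: np.ndarray, grid: GridSpec, path) -> None:
    """Write a single-band float32 GeoTIFF, north-up, cell-center registered.

    The tie point anchors raster pixel (0,0) at the north-west cell's outer
    corner, matching the GDAL area convention for a cell-center grid.
    """
    import tifffile

    arr = np.asarray(arr, dtype=np.float32)
    if arr.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    # row 0 of a GeoTIFF is the northernmost; our arrays are south-up
    north_up = arr[::-1, :]
    west = grid.lon_min - grid.cell_size_lon / 2.0
    north = grid.lat_max + grid.cell_size_lat / 2.0
    scale = (grid.cell_size_lon, grid.cell_size_lat, 0.0)
    tiepoint = (0.0, 0.0, 0.0, west, north, 0.0)
    tifffile.imwrite(
        path,
        north_up,
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, scale, True),
            (_TAG_TIEPOINT, "d", 6, tiepoint, True),
        ],
    )


def read_geotiff(path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    north-up, cell-area-registered regular grid)."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        north_up = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"{path} lacks GeoTIFF georeferencing tags")
    sx, sy, _ = tags[_TAG_PIXEL_SCALE]
    _, _, _, west, north, _ = tags[_TAG_TIEPOINT]
    n_lat, n_lon = north_up.shape
    grid = GridSpec(
        lat_min=north - n_lat * sy + sy / 2.0,
        lon_min=west + sx / 2.0,
        n_lat=n_lat,
        n_lon=n_lon,
        cell_size_lat=sy,
        cell_size_lon=sx,
    )
    return north_up[::-1, :].astype(np.float32), grid


# ---------------------------------------------------------------------------
# risk-map stacks
# ---------------------------------------------------------------------------

def risk_stack(grid: GridSpec, dates, fnr: np.ndarray) -> xr.DataArray:
    """Build a daily FNR stack DataArray with dims (time, lat, lon)."""
    return xr.DataArray(
        np.asarray(fnr, dtype=np.float32),
        dims=("time", "lat", "lon"),
        coords={"time": pd.DatetimeIndex(dates), "lat": grid.lat_centers, "lon": grid.lon_centers},
        name="fnr",
    )


def write_risk_maps(stack: xr.DataArray, path, format: str = "netcdf") -> list[Path]:
    """Persist a daily FNR stack; returns the files written.

    ``netcdf``: one file.  ``geotiff``: ``<path>/<YYYY-MM-DD>.tif`` per day.
    ``csv``: long-format ``date,lat,lon,fnr`` rows.
    """
    path = Path(path)
    grid = GridSpec.from_coords(stack.lat.values, stack.lon.values)
    dates = pd.DatetimeIndex(stack.time.values)
    if format == "netcdf":
        stack.astype(np.float32).to_dataset(name="fnr").to_netcdf(path, engine="scipy")
        return [path]
    if format == "geotiff":
        path.mkdir(parents=True, exist_ok=True)
        out = []
        for k, d in enumerate(dates):
            f = path / f"{d.strftime('%Y-%m-%d')}.tif"
            write_geotiff(stack.values[k], grid, f)
            out.append(f)
        return out
    if format == "csv":
        lat = np.repeat(grid.lat_centers, grid.n_lon)
        lon = np.tile(grid.lon_centers, grid.n_lat)
        frames = []
        for k, d in enumerate(dates):
            frames.append(
                pd.DataFrame(
                    {
                        "date": d.strftime("%Y-%m-%d"),
                        "lat": lat,
                        "lon": lon,
                        "fnr": stack.values[k].ravel(),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return [path]
    raise ValueError(f"unsupported risk-map format: {format!r}")


def read_risk_maps(path, format: str = "netcdf") -> xr.DataArray:
    path = Path(path)
    if format == "netcdf":
        ds = xr.open_dataset(path, engine="scipy", decode_timedelta=False)
        return ds["fnr"].load()
    if format == "geotiff":
        files = sorted(path.glob("*.tif"))
        arrs, grid = [], None
        for f in files:
            a, g = read_geotiff(f)
            grid = grid or g
            arrs.append(a)
        dates = pd.DatetimeIndex([pd.Timestamp(f.stem) for f in files])
        return risk_stack(grid, dates, np.stack(arrs))
    if format == "csv":
        df = pd.read_csv(path, parse_dates=["date"])
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        dates = pd.DatetimeIndex(np.sort(df["date"].unique()))
        grid = GridSpec.from_coords(lats, lons)
        pivot = df.sort_values(["date", "lat", "lon"])
        arr = pivot["fnr"].to_numpy(dtype=np.float32).reshape(len(dates), len(lats), len(lons))
        return risk_stack(grid, dates, arr)
    raise ValueError(f"unsupported risk-map format: {format!r}")


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _overlap_matrix(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Fraction of each source interval falling in each destination interval.

    Returns a (n_src, n_dst) matrix whose rows sum to <= 1 (1 when the source
    interval lies fully inside the destination extent).
    """
    lo = np.maximum.outer(src_edges[:-1], dst_edges[:-1])
    hi = np.minimum.outer(src_edges[1:], dst_edges[1:])
    overlap = np.clip(hi - lo, 0.0, None)
    width = np.diff(src_edges)[:, None]
    return overlap / width


def _edges(centers: np.ndarray, size: float) -> np.ndarray:
    return np.concatenate([centers - size / 2.0, [centers[-1] + size / 2.0]])


def resample_population(counts: np.ndarray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    """Area-weighted resampling of population *counts* (persons conserve).

    Each source cell's persons are split among destination cells in
    proportion to fractional overlap of the cell rectangles.
    """
    counts = np.asarray(counts, dtype=float)
    wlat = _overlap_matrix(_edges(src.lat_centers, src.cell_size_lat),
                           _edges(dst.lat_centers, dst.cell_size_lat))
    wlon = _overlap_matrix(_edges(src.lon_centers, src.cell_size_lon),
                           _edges(dst.lon_centers, dst.cell_size_lon))
    return wlat.T @ counts @ wlon


def read_population(paths_by_year: dict[int, str], grid: GridSpec) -> PopulationGrid:
    """Load per-census-year GeoTIFFs, resampling persons onto the model grid."""
    years = sorted(paths_by_year)
    rasters = []
    for y in years:
        arr, src = read_geotiff(paths_by_year[y])
        if src.to_dict() == grid.to_dict():
            rasters.append(arr.astype(float))
        else:
            rasters.append(resample_population(arr, src, grid))
    return PopulationGrid(grid=grid, census_years=years, density=np.stack(rasters))
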