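"""Grid geometry, point snapping, and raster/observation I/O round trips."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from vectorhab import grid_io
from vectorhab.grid_io import (
    GridSpec,
    GridError,
    LandMask,
    PopulationGrid,
    read_climate_netcdf,
    read_geotiff,
    read_observations,
    read_risk_maps,
    resample_population,
    risk_stack,
    write_climate_netcdf,
    write_geotiff,
    write_risk_maps,
)

from conftest import make_toy_cube


class TestGridSpec:
    def test_geometry(self):
        g = GridSpec(lat_min=-50.0, lon_min=-100.0, n_lat=5, n_lon=8, cell_size_lat=1.0, cell_size_lon=2.0)
        assert g.lat_max == -46.0
        assert g.shape == (5, 8)
        assert np.allclose(g.lat_centers, [-50, -49, -48, -47, -46])

    @pytest.mark.parametrize("kwargs", [
        dict(lat_min=0, lon_min=0, n_lat=1, n_lon=1, cell_size_lat=0),
        dict(lat_min=89.9, lon_min=0, n_lat=5, n_lon=1),   # centers past the pole
        dict(lat_min=0, lon_min=181.0, n_lat=1, n_lon=1),  # lon out of range
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(GridError):
            GridSpec(**{"cell_size_lat": 0.25, "cell_size_lon": 0.25, **kwargs})

    def test_snap_at_center_is_identity(self):
        g = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=10, n_lon=10)
        assert g.snap_to_cell(0.5, 0.75) == (2, 3)

    def test_snap_tie_breaks_to_lower_index(self):
        g = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=10, n_lon=10)
        # exactly halfway between centers 0.0 and 0.25
        assert g.snap_to_cell(0.125, 0.125) == (0, 0)

    def test_snap_quarter_degree_example(self):
        g = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=4, n_lon=4)
        assert g.snap_to_cell(0.10, 0.10) == (0, 0)

    def test_snap_outside_extent_errors(self):
        g = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=4, n_lon=4)
        with pytest.raises(GridError):
            g.snap_to_cell(5.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(lat=st.floats(-0.124, 2.37), lon=st.floats(-0.124, 2.37))
    def test_snap_matches_exhaustive_nearest_center(self, lat, lon):
        g = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=10, n_lon=10)
        i, j = g.snap_to_cell(lat, lon)
        la, lo = np.meshgrid(g.lat_centers, g.lon_centers, indexing="ij")
        d2 = (la - lat) ** 2 + (lo - lon) ** 2
        assert d2[i, j] <= d2.min() + 1e-12


class TestObservations:
    def _write(self, tmp_path, rows):
        p = tmp_path / "obs.csv"
        p.write_text("species,date,latitude,longitude\n" + "\n".join(rows) + "\n")
        return p

    def test_well_formed_rows_parse_and_snap(self, tmp_path, toy_grid):
        p = self._write(tmp_path, [
            "Aedes aegypti,2020-01-05,0.1,0.1",
            "Aedes aegypti,2020-01-06,0.5,0.75",
            "Aedes aegypti,2020-01-07,0.0,0.0",
        ])
        df, rep = read_observations(p, toy_grid)
        assert len(df) == 3 and rep.n_kept == 3
        assert df.loc[1, "cell_row"] == 2 and df.loc[1, "cell_col"] == 3
        assert (df.label == 1).all()

    def test_bad_latitude_skipped_with_count(self, tmp_path, toy_grid):
        p = self._write(tmp_path, [
            "x,2020-01-05,95.0,0.1",
            "x,2020-01-05,0.1,0.1",
        ])
        df, rep = read_observations(p, toy_grid)
        assert len(df) == 1
        assert rep.skipped.get("invalid coordinates") == 1

    def test_insufficient_history_skipped(self, tmp_path, toy_grid):
        # 10-day toy cube starting 2020-01-01; seq_len 5 -> first usable date 2020-01-06
        cube = make_toy_cube()
        p = self._write(tmp_path, [
            "x,2020-01-03,0.1,0.1",
            "x,2020-01-06,0.1,0.1",
        ])
        df, rep = read_observations(p, toy_grid, dates_available=cube.dates, seq_len=5)
        assert len(df) == 1
        assert rep.skipped.get("insufficient history") == 1

    def test_missing_column_is_hard_error(self, tmp_path, toy_grid):
        p = tmp_path / "obs.csv"
        p.write_text("species,date,latitude\nx,2020-01-01,0.0\n")
        with pytest.raises(ValueError, match="longitude"):
            read_observations(p, toy_grid)

    def test_empty_file_is_hard_error(self, tmp_path, toy_grid):
        p = tmp_path / "obs.csv"
        p.write_text("species,date,latitude,longitude\n")
        with pytest.raises(ValueError, match="empty"):
            read_observations(p, toy_grid)


class TestClimateIO:
    def test_netcdf_round_trip(self, tmp_path, toy_cube):
        f = tmp_path / "clim.nc"
        write_climate_netcdf(toy_cube, f)
        back = read_climate_netcdf(f)
        for v in grid_io.RAW_VARS:
            np.testing.assert_allclose(back.var(v), toy_cube.var(v))
        assert back.dates.equals(toy_cube.dates)

    def test_kelvin_converted_by_units_metadata(self, tmp_path, toy_cube):
        ds = toy_cube.data.copy()
        ds["tmean"] = ds["tmean"] + 273.15
        ds["tmean"].attrs["units"] = "K"
        f = tmp_path / "clim.nc"
        ds.to_netcdf(f, engine="scipy")
        back = read_climate_netcdf(f)
        np.testing.assert_allclose(back.var("tmean"), toy_cube.var("tmean"), rtol=1e-12)

    def test_date_gap_is_hard_error(self, toy_cube):
        ds = toy_cube.data.isel(time=[0, 1, 2, 4, 5])  # drop day 4
        with pytest.raises(ValueError, match="2020-01-04"):
            grid_io.ClimateCube(ds)


class TestGeoTiff:
    def test_round_trip_values_and_georeference(self, tmp_path, toy_grid):
        arr = np.arange(12, dtype=np.float32).reshape(3, 4)
        f = tmp_path / "x.tif"
        write_geotiff(arr, toy_grid, f)
        back, grid = read_geotiff(f)
        np.testing.assert_array_equal(back, arr)
        assert grid.to_dict() == pytest.approx(toy_grid.to_dict())


class TestRiskMaps:
    @pytest.fixture
    def stack(self, toy_grid):
        rng = np.random.default_rng(0)
        fnr = rng.random((2, 3, 4)).astype(np.float32)
        return risk_stack(toy_grid, pd.date_range("2021-06-01", periods=2), fnr)

    @pytest.mark.parametrize("fmt,name", [
        ("netcdf", "s.nc"), ("geotiff", "tifs"), ("csv", "s.csv"),
    ])
    def test_round_trip(self, tmp_path, stack, fmt, name):
        write_risk_maps(stack, tmp_path / name, fmt)
        back = read_risk_maps(tmp_path / name, fmt)
        np.testing.assert_array_equal(back.values, stack.values)

    def test_csv_row_count(self, tmp_path, stack):
        write_risk_maps(stack, tmp_path / "s.csv", "csv")
        df = pd.read_csv(tmp_path / "s.csv")
        assert len(df) == 2 * 3 * 4

    def test_unsupported_format_errors(self, tmp_path, stack):
        with pytest.raises(ValueError, match="format"):
            write_risk_maps(stack, tmp_path / "s.xyz", "parquet")


class TestPopulation:
    def test_resampling_conserves_persons(self):
        src = GridSpec(lat_min=0.125, lon_min=0.125, n_lat=8, n_lon=8,
                       cell_size_lat=0.25, cell_size_lon=0.25)
        dst = GridSpec(lat_min=0.25, lon_min=0.25, n_lat=4, n_lon=4,
                       cell_size_lat=0.5, cell_size_lon=0.5)
        rng = np.random.default_rng(3)
        counts = rng.uniform(0, 100, (8, 8))
        out = resample_population(counts, src, dst)
        assert abs(out.sum() - counts.sum()) / counts.sum() < 1e-3
        assert out.shape == (4, 4)

    def test_nested_resampling_is_exact_block_sum(self):
        src = GridSpec(lat_min=0.125, lon_min=0.125, n_lat=4, n_lon=4,
                       cell_size_lat=0.25, cell_size_lon=0.25)
        dst = GridSpec(lat_min=0.25, lon_min=0.25, n_lat=2, n_lon=2,
                       cell_size_lat=0.5, cell_size_lon=0.5)
        counts = np.arange(16, dtype=float).reshape(4, 4)
        out = resample_population(counts, src, dst)
        expected = counts.reshape(2, 2, 2, 2).sum(axis=(1, 3))
        np.testing.assert_allclose(out, expected)

    def test_population_grid_validation(self, toy_grid):
        with pytest.raises(ValueError, match="two census"):
            PopulationGrid(grid=toy_grid, census_years=[2000],
                           density=np.zeros((1, 3, 4)))
        with pytest.raises(ValueError, match="non-negative"):
            PopulationGrid(grid=toy_grid, census_years=[2000, 2010],
                           density=-np.ones((2, 3, 4)))


class TestLandMask:
    def test_all_ocean_rejected(self, toy_grid):
        with pytest.raises(ValueError, match="no land"):
            LandMask(grid=toy_grid, is_land=np.zeros((3, 4), dtype=bool))

    def test_land_indices_within_bounds(self, toy_grid):
        m = LandMask(grid=toy_grid, is_land=np.eye(3, 4, dtype=bool))
        idx = m.land_indices
        assert (idx[:, 0] < 3).all() and (idx[:, 1] < 4).all()
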