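"""Shared fixtures: toy cubes for unit tests and one session-scoped default
synthetic world + trained model reused by the end-to-end suites."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from vectorhab import ffnn, sampling
from vectorhab import features as feat
from vectorhab import synthetic_world as sw
from vectorhab.grid_io import ClimateCube, GridSpec, LandMask


def make_toy_cube(n_days=10, n_lat=3, n_lon=4, start="2020-01-01", seed=0):
    """Small deterministic climate cube with plausible value ranges."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(lat_min=0.0, lon_min=0.0, n_lat=n_lat, n_lon=n_lon)
    dates = pd.date_range(start, periods=n_days, freq="D")
    shape = (n_days, n_lat, n_lon)
    tmean = 20 + rng.normal(0, 3, shape)
    ds = xr.Dataset(
        {
            "tmean": (("time", "lat", "lon"), tmean),
            "tmax": (("time", "lat", "lon"), tmean + 4),
            "tmin": (("time", "lat", "lon"), tmean - 4),
            "tdew": (("time", "lat", "lon"), tmean - 5),
            "precip_hourly": (("time", "lat", "lon"), np.abs(rng.normal(0.1, 0.05, shape))),
            "uwind": (("time", "lat", "lon"), rng.normal(2, 1, shape)),
            "vwind": (("time", "lat", "lon"), rng.normal(0, 1, shape)),
        },
        coords={"time": dates, "lat": grid.lat_centers, "lon": grid.lon_centers},
    )
    return ClimateCube(ds)


@pytest.fixture
def toy_cube():
    return make_toy_cube()


@pytest.fixture
def toy_grid():
    return GridSpec(lat_min=0.0, lon_min=0.0, n_lat=3, n_lon=4)


# ---------------------------------------------------------------------------
# the default synthetic world: generated once per session
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_world():
    cfg = sw.WorldConfig(seed=1)
    cube, mask, obs, pop, hab = sw.generate_world(cfg)
    return {"config": cfg, "cube": cube, "mask": mask, "obs": obs,
            "pop": pop, "hab": hab}


@pytest.fixture(scope="session")
def default_derived(default_world):
    return feat.derive_all(default_world["cube"])


@pytest.fixture(scope="session")
def default_dataset(default_world, default_derived):
    scfg = sampling.SamplingConfig(absence_ratio=0.2, rng_seed=1)
    return sampling.build_dataset(
        default_world["obs"], scfg, default_world["mask"], default_derived, seq_len=60
    )


@pytest.fixture(scope="session")
def default_split(default_dataset):
    rng = np.random.default_rng(1)
    train_set, test_set = sampling.split_random(default_dataset, 0.2, rng)
    return train_set, test_set


@pytest.fixture(scope="session")
def trained_model(default_split):
    """The study-conditions model: seq_len 60, absence ratio 0.2, seed 1."""
    train_set, _ = default_split
    cfg = ffnn.ModelConfig(seed=1, seq_len=60, max_epochs=400)
    return ffnn.fit_pipeline(train_set, cfg)
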