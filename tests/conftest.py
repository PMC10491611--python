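import numpy as np
import pytest

from peatenvelope.grids import GridSpec, MonthlyClimatology, RasterField
from peatenvelope.synth import SynthConfig, make_truth


@pytest.fixture(scope="session")
def truth_clean():
    """Noise-free 40x40 synthetic bundle with known thresholds."""
    return make_truth(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def truth_noisy():
    """100x100 bundle (10,000 cells) with 10% flip noise."""
    return make_truth(SynthConfig(seed=3, n_lat=100, n_lon=100,
                                  flip_noise=0.1))


@pytest.fixture
def small_grid():
    return GridSpec(lat_min=30.0, lat_max=31.0, lon_min=100.0,
                    lon_max=101.0, resolution=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_cell_climatology(lat=33.5, mat=1.4, amplitude=9.0,
                            map_mm=400.0, sun_mean=0.42, sun_seasonal=0.12):
    """One-cell monthly climatology with a sinusoidal annual cycle."""
    res = 1.0 / 6.0
    grid = GridSpec(lat_min=lat - res / 2, lat_max=lat + res / 2,
                    lon_min=102.0, lon_max=102.0 + res)
    months = np.arange(12)
    cyc = np.cos(2 * np.pi * (months - 6) / 12.0)
    tmp = (mat + amplitude * cyc)[:, None, None]
    w = 1 + 0.8 * cyc
    pre = (map_mm * w / w.sum())[:, None, None]
    sun = np.clip(sun_mean - sun_seasonal * cyc, 0, 1)[:, None, None]
    return MonthlyClimatology(grid=grid, tmp=tmp, pre=pre, sun=sun)


def constant_elevation(grid, value):
    return RasterField(grid=grid, values=np.full(grid.shape, float(value)),
                       units="m", name="elevation")
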