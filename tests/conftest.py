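import numpy as np
import pytest

from marshline.dynamics import SimParams, Surfaces
from marshline.grid import Grid, GridMeta
from marshline.synthetic import SynthConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_rows=100, n_cols=100, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture()
def flat_surfaces():
    """Spatially uniform inputs for analytic dynamics tests."""
    def make(shape, tss=0.0, ab=0.0, bg=0.0):
        return Surfaces(tss=np.full(shape, float(tss)),
                        ab_biomass=np.full(shape, float(ab)),
                        bg_biomass=np.full(shape, float(bg)))
    return make


def make_grid(data, cell_size=2.0, nodata=-9999.0) -> Grid:
    data = np.asarray(data)
    meta = GridMeta(data.shape[0], data.shape[1], cell_size, nodata=nodata)
    return Grid(data, meta)


@pytest.fixture()
def grid_factory():
    return make_grid
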