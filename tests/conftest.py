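import numpy as np
import pytest

from windcape import CapeField, GridSpec, SyntheticScenario, make_cape_field


@pytest.fixture
def small_grid():
    return GridSpec(resolution=0.25, bounds=(-70.0, -64.0, -6.0, 0.0))


@pytest.fixture
def small_scenario(small_grid):
    return SyntheticScenario(seed=7, grid=small_grid, correlation_length_deg=1.0)


@pytest.fixture
def small_field(small_scenario):
    return make_cape_field(small_scenario)


@pytest.fixture
def uniform_field(small_grid):
    def _make(value, provenance=""):
        shape = (small_grid.n_lat, small_grid.n_lon)
        return CapeField.from_grid(small_grid, np.full(shape, float(value)), provenance=provenance)

    return _make
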