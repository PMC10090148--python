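import numpy as np
import pytest

from escost.biomes import BiomeScheme
from escost.synthetic import GridSpec, ScenarioSpec, generate_landscape


@pytest.fixture(scope="session")
def scheme():
    return BiomeScheme()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(n_rows=20, n_cols=20, cell_area_ha=50.0, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_grid, scheme):
    scen = ScenarioSpec.preset("GFDL-SSP126", small_grid)
    return generate_landscape(small_grid, scen, scheme)


def constant_scenario(grid, flip_rate, nee_trend=0.0, name="const",
                      **kwargs):
    """Scenario with spatially constant flip rate and NEE trend."""
    return ScenarioSpec(
        name=name,
        flip_rate_map=np.full(grid.shape, float(flip_rate)),
        nee_trend_map=np.full(grid.shape, float(nee_trend)),
        **kwargs,
    )
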