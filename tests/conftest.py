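import numpy as np
import pytest

from exposim import RegionConfig, build_geography


@pytest.fixture(scope="session")
def small_config():
    return RegionConfig(
        n_districts=4,
        n_neighbourhoods=8,
        n_tracts=120,
        n_background_monitors=4,
        n_roadside_monitors=2,
        n_grid_points=25,
        n_mothers=300,
        region_extent_km=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_region(small_config):
    return build_geography(small_config)


@pytest.fixture(scope="session")
def desk_region():
    """Mid-size region used by the pipeline-level tests."""
    return build_geography(RegionConfig(
        n_districts=5,
        n_neighbourhoods=20,
        n_tracts=400,
        n_background_monitors=5,
        n_roadside_monitors=3,
        n_grid_points=49,
        n_mothers=1000,
        seed=11,
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
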