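import numpy as np
import pytest

from sdbiomass.geodata import GridSpec
from sdbiomass.pipeline import run_pipeline
from sdbiomass.synthetic import LandscapeConfig, generate_bundle


def small_config(seed: int = 7, **kwargs) -> LandscapeConfig:
    """A fast bundle config for unit tests: 60x60 grid, 2 years, 4 polygons/yr."""
    defaults = dict(
        seed=seed,
        spec=GridSpec(origin_x=500_000.0, origin_y=4_200_000.0, n_rows=60, n_cols=60),
        years=(2012, 2013),
        n_polygons_per_year=4,
    )
    defaults.update(kwargs)
    return LandscapeConfig(**defaults)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size default landscape with a noisy reference raster."""
    return generate_bundle(LandscapeConfig(seed=11), reference_noise_sd_log=0.5)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle)


@pytest.fixture()
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
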