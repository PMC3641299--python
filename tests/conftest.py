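import numpy as np
import pytest

from degrisk.geodata import Grid, GridSpec
from degrisk.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec5():
    return GridSpec(5, 5, 0.0, 1250.0, 250.0, "test")


def random_grid(rng, n_rows=20, n_cols=20, cell_size=250.0, mask_rate=0.1,
                crs="test") -> Grid:
    spec = GridSpec(n_rows, n_cols, 0.0, n_rows * cell_size, cell_size, crs)
    values = rng.normal(size=spec.shape)
    mask = rng.random(spec.shape) < mask_rate
    return Grid(spec, values, mask)


@pytest.fixture(scope="session")
def small_scenario():
    """One 40x40 default-noise scenario shared across tests."""
    return generate_scenario(ScenarioConfig(n_rows=40, n_cols=40, seed=11))


@pytest.fixture(scope="session")
def clean_scenario():
    """Noise-free, gap-free 40x40 scenario for exact closed-loop checks."""
    cfg = ScenarioConfig(n_rows=40, n_cols=40, seed=11, noise_sigma=0.0,
                         missing_rate=0.0, low_quality_rate=0.0)
    return generate_scenario(cfg)
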