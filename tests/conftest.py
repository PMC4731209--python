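import numpy as np
import pytest
from hypothesis import settings

from ignoscore.beta_glm import MCMCSettings
from ignoscore.grid import GridSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_grid() -> GridSpec:
    """5x5 grid of 10 km cells with origin at (0, 0)."""
    return GridSpec(x_min=0.0, y_min=0.0, cell_size=10_000.0, n_rows=5, n_cols=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def fast_mcmc() -> MCMCSettings:
    """Short but converging chains for unit-level fits."""
    return MCMCSettings(iterations=800, burn_in=800, chains=2, seed=7)
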