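import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from nanoclust import RGrid, Window


@pytest.fixture
def window() -> Window:
    return Window(1000.0, 1000.0)


@pytest.fixture
def coarse_grid() -> RGrid:
    """A short radius grid for tests that do not need 1 nm resolution."""
    return RGrid(np.array([5.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0, 240.0]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
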