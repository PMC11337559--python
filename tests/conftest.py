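import numpy as np
import pytest

from caplex.curves import TimeGrid
from caplex.registry import load_registry
from caplex.synthetic import AIFSpec, gen_aif


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def grid():
    """Standard dynamic grid: 2 s interval over 420 s (211 samples)."""
    return TimeGrid.uniform(2.0, 420.0)


@pytest.fixture(scope="session")
def aif(grid):
    return gen_aif(grid, AIFSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
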