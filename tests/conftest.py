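import numpy as np
import pytest

from apostab import paper_default
from apostab import synthetic


@pytest.fixture(scope="session")
def scenario():
    return paper_default()


@pytest.fixture(scope="session")
def grid(scenario):
    return scenario.temperature_grid()


@pytest.fixture(scope="session")
def mut_curve(scenario, grid):
    """Noiseless default mutant melt curve (Tm 47 °C)."""
    return synthetic.simulate_melt_curve(scenario.mutant, grid, well="B12")


@pytest.fixture(scope="session")
def wt_curve(scenario, grid):
    """Noiseless default WT melt curve (Tm 65 °C)."""
    return synthetic.simulate_melt_curve(scenario.wt, grid, well="A12")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
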