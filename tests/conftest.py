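import numpy as np
import pytest

from cinwgs.coverage import build_panel
from cinwgs.genome import ChromosomeArm, build_bin_grid
from cinwgs.synthetic import TOY_TP53, SimConfig, simulate_controls, toy_genome


@pytest.fixture(scope="session")
def toy_grid():
    return toy_genome()


@pytest.fixture(scope="session")
def tiny_grid():
    """Two arms of one chromosome, 10 bins of 100 bp each."""
    arms = [
        ChromosomeArm("tp", "chrT", 0, 500),
        ChromosomeArm("tq", "chrT", 600, 1100),
    ]
    return build_bin_grid(arms, bin_size=100)


@pytest.fixture(scope="session")
def default_sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def toy_controls(default_sim_config, toy_grid):
    return simulate_controls(default_sim_config, toy_grid)


@pytest.fixture(scope="session")
def toy_panel(toy_controls, toy_grid):
    return build_panel(toy_controls, toy_grid, loci=[TOY_TP53])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
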