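import numpy as np
import pytest

from alphafilm import mc


@pytest.fixture(scope="session")
def ebt3_grid_400k():
    """Moderate-statistics EBT3 run shared by profile/ROI tests."""
    cfg = mc.SimulationConfig(stack=mc.film_stack("EBT3"))
    return mc.run_simulation(cfg, 400_000, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
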