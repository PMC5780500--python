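import numpy as np
import pytest

import caretta as ct


@pytest.fixture(scope="session")
def grid():
    return ct.default_grid()


@pytest.fixture(scope="session")
def baseline():
    """One default-configuration simulated baseline, shared across tests."""
    cfg = ct.SimulationConfig(seed=1)
    panel, truth = ct.simulate_baseline(cfg)
    return cfg, panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20180123)
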