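import numpy as np
import pytest

from burstcoast.core_model import Arena, LightParams
from burstcoast.io import load_params
from burstcoast.simulator import SimulationRun, run_simulation


@pytest.fixture(scope="session")
def params_single():
    """Packaged single-fish defaults at the brightest condition."""
    return load_params(1, 50.0)


@pytest.fixture(scope="session")
def params_pair():
    return load_params(2, 50.0)


@pytest.fixture(scope="session")
def params_group5():
    return load_params(5, 50.0)


@pytest.fixture(scope="session")
def harness_params():
    """A free-standing parameter vector used by recovery tests (values are
    test-harness choices, not any condition's defaults)."""
    return LightParams(
        label=50.0, gamma_R=0.3, alpha=0.67, gamma_w=4.0, l_w=60.0,
        tau0=0.79, tau_bar=0.45, tau_min=0.22, v_bar=159.0,
        gamma_att=0.3, l_att=120.0, d_att=30.0,
        gamma_ali=0.3, l_ali=100.0, d_ali=30.0,
        gamma_m=0.6, l_m=60.0, d_m=30.0, l_c=2.0, l_bar=50.0)


@pytest.fixture(scope="session")
def single_run(params_single):
    """300 s single-fish simulation shared across tests."""
    return run_simulation(SimulationRun(n_fish=1, duration=300.0, seed=9,
                                        params=params_single))


@pytest.fixture(scope="session")
def group5_run(params_group5):
    return run_simulation(SimulationRun(n_fish=5, duration=120.0, seed=4,
                                        params=params_group5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
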