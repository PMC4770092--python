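import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lidforce.constants import Constants
from lidforce.elasticity import DEFAULT_DNA, TetherModel, WLCParams
from lidforce.synthetic import TraceSimConfig, render_trace, simulate_state_path

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> Constants:
    return Constants()


@pytest.fixture(scope="session")
def tether() -> TetherModel:
    return TetherModel(dna=DEFAULT_DNA, trap_stiffness_1=0.3, trap_stiffness_2=0.3)


@pytest.fixture(scope="session")
def dna() -> WLCParams:
    return DEFAULT_DNA


@pytest.fixture(scope="session")
def short_synthetic():
    """A 6 s rendered two-state trace with ~150 transitions and its truth."""
    config = TraceSimConfig(seed=123, duration=6.0, ligand_concentration=150.0)
    path = simulate_state_path(config)
    rendered = render_trace(path, config)
    return config, path, rendered


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
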