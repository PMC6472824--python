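import numpy as np
import pytest

from bumptraj.pipeline import run_geometry_experiment
from bumptraj.simulate import SimulationConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Three intervals, three repetitions: fast but structurally complete."""
    return SimulationConfig(
        target_intervals_ms=(450, 650, 1000), n_repetitions=3, seed=7
    )


@pytest.fixture(scope="session")
def expanding_results():
    """Full expanding-regime geometry experiments for seeds 1..5."""
    return [
        run_geometry_experiment(SimulationConfig(regime="expanding", seed=s))
        for s in range(1, 6)
    ]


@pytest.fixture(scope="session")
def static_results():
    """Full static-regime geometry experiments for seeds 1..5."""
    return [
        run_geometry_experiment(SimulationConfig(regime="static", seed=s))
        for s in range(1, 6)
    ]
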