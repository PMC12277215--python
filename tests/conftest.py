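import numpy as np
import pytest

from damperopt.fixtures import baseline_gait_preset
from damperopt.gait_model import simulate


@pytest.fixture(scope="session")
def level_preset():
    return baseline_gait_preset("level")


@pytest.fixture(scope="session")
def downhill_preset():
    return baseline_gait_preset("downhill")


@pytest.fixture(scope="session")
def level_result(level_preset):
    """Device-free simulation of the packaged level-ground preset."""
    theta, anthro, scenario = level_preset
    return simulate(None, theta, scenario, anthro)


@pytest.fixture(scope="session")
def downhill_result(downhill_preset):
    theta, anthro, scenario = downhill_preset
    return simulate(None, theta, scenario, anthro)


@pytest.fixture(scope="session")
def level_context():
    """Optimized no-device baseline context for design evaluations."""
    from damperopt.outer_loop import make_baseline_context

    return make_baseline_context("level")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
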