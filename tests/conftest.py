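import numpy as np
import pytest

from kernelset import REFERENCE_HYBRIDS, default_shading_config


@pytest.fixture(scope="session")
def hybrids():
    return REFERENCE_HYBRIDS


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_shading_sim():
    """One modest shading run shared by read-only tests."""
    from kernelset import simulate_shading_experiment
    return simulate_shading_experiment(default_shading_config(seed=11))
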