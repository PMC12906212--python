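import numpy as np
import pytest

from shallowbrain.decision import ModelBundle


@pytest.fixture(scope="session")
def ff_model() -> ModelBundle:
    """Trained feedforward-variant model (CNN cortex + perceptron subcortex)."""
    return ModelBundle.build_ff(seed=0)


@pytest.fixture(scope="session")
def pc_model() -> ModelBundle:
    """Trained predictive-coding-variant model (PC hierarchy + random E/I net)."""
    return ModelBundle.build_pc(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
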