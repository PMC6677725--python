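import numpy as np
import pytest

from laminarsc import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A modest VG-only synthetic session shared by unit tests."""
    cfg = GeneratorConfig(seed=5, n_trials=40, task_mix={"VG": 1.0})
    return generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
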