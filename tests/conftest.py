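import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def sim_config():
    from xenomir.simulate import SimConfig

    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def sim_refs(sim_config):
    from xenomir.simulate import gen_references

    return gen_references(sim_config)


@pytest.fixture(scope="session")
def sim_sample(sim_config, sim_refs):
    from xenomir.simulate import gen_sample

    return gen_sample(sim_refs, sim_config)
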