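import numpy as np
import pytest

from mycolib.qc import run_qc
from mycolib.reference import ReferenceDB
from mycolib.simulate import (
    SimulationConfig,
    generate_metacommunity,
    sample_clone_library,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_community(default_config):
    return generate_metacommunity(default_config)


@pytest.fixture(scope="session")
def default_library(default_community, default_config):
    return sample_clone_library(default_community, default_config)


@pytest.fixture(scope="session")
def default_reference(default_community):
    return ReferenceDB.from_metacommunity(default_community)


@pytest.fixture(scope="session")
def default_qc(default_library, default_reference):
    records, _ = default_library
    return run_qc(records, default_reference)


@pytest.fixture(scope="session")
def noise_free_setup():
    """Noise-free library: no chimeras, no PCR errors."""
    cfg = SimulationConfig(seed=7, chimera_rate=0.0, pcr_error_rate=0.0)
    community = generate_metacommunity(cfg)
    records, truth = sample_clone_library(community, cfg)
    return cfg, community, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
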