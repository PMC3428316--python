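import numpy as np
import pytest

from rulerarray import RunConfig
from rulerarray.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def small_sim_config():
    """Small, fast simulation: 200 kb genome, default array geometry."""
    return SimulationConfig(genome_length=200_000, seed=11)


@pytest.fixture
def run_config():
    cfg = RunConfig()
    cfg.sim.genome_length = 200_000
    cfg.sim.seed = 11
    return cfg


def make_noiseless_config(**kw) -> SimulationConfig:
    base = dict(genome_length=200_000, noise_sd_log2=0.0, affinity_sd_log2=0.0,
                multi_hit_fraction=0.0, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture
def noiseless_config():
    return make_noiseless_config()
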