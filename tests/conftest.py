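import numpy as np
import pytest

from longcace import SimConfig, generate_dataset
from longcace.means import ModelParameters


TRUE_BETA = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
TRUE_GAMMA = np.array([1 / 9] * 5 + [4 / 9])


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(base_seed=20240917)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """One default-design synthetic trial (n=300, complete data)."""
    return generate_dataset(sim_config, replicate_index=0)


@pytest.fixture(scope="session")
def big_dataset():
    """A large synthetic trial for consistency checks."""
    cfg = SimConfig(n=100_000, base_seed=555)
    return generate_dataset(cfg, replicate_index=0)


@pytest.fixture(scope="session")
def true_params(sim_config):
    return ModelParameters(
        alpha=sim_config.alpha_true,
        beta=sim_config.beta_true,
        gamma=np.asarray(sim_config.gamma_true),
        sigma=64.0 * np.eye(5),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
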