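import numpy as np
import pytest

from hippotune import AnalysisConfig, SimParams, simulate_behavior, simulate_session


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim(cfg):
    """A short 6-cell session (4 x 30-s blocks) with ground truth."""
    params = SimParams(n_cells=6, n_blocks=4, block_s=30.0)
    return simulate_session(params, cfg, seed=11)


@pytest.fixture(scope="session")
def behavior(cfg):
    params = SimParams(n_blocks=4, block_s=60.0)
    return simulate_behavior(params, cfg, np.random.default_rng(3))
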