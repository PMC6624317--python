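import numpy as np
import pytest

from startshift import SimConfig, simulate
from startshift.model import PipelineConfig


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene synthetic dataset shared by read-only tests."""
    return simulate(SimConfig(n_genes=40), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
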