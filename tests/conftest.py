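import pytest

from gps_periscan.config import PipelineConfig
from gps_periscan.synthetic_data import simulate


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def dataset(config):
    """One full synthetic dataset shared by read-only tests."""
    return simulate(config, seed=1)
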