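import pytest

from chondrosim import default_config
from chondrosim.config import build_economics, build_params
from chondrosim.population import default_life_table, sample_cohort


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def params(cfg):
    return build_params(cfg)


@pytest.fixture(scope="session")
def economics_blocks(cfg):
    return build_economics(cfg)


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(300, seed=7)


@pytest.fixture(scope="session")
def big_cohort():
    return sample_cohort(10_000, seed=11)
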