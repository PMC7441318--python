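import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from consangcnv import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    """Small 2-chromosome genome/map (150 cM each, 1 Mb per cM)."""
    return syn.toy_genome(2, 150)


@pytest.fixture(scope="session")
def full_genome():
    """Default 22-autosome synthetic genome (~3,538 cM)."""
    return syn.synthetic_genome(22)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
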