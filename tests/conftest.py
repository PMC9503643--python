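import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    from pacscope import make_reference

    return make_reference(length=2_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def headful_sim():
    """One moderate headful-pac simulation shared across detection tests."""
    from pacscope import simulate

    return simulate("headful_pac", genome_length=40_000, pac_position=12_345, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
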