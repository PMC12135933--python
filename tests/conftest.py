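import pytest
from hypothesis import HealthCheck, settings

from prophagedyn import SimConfig, make_genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_genome(default_cfg):
    return make_genome(default_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down configuration for fast integration tests."""
    return SimConfig(
        chromosome_length=20_000,
        prophage_length=12_000,
        prophage_start=3_000,
        vr_offset=8_000,
        hazard_region=5_000,
        hazard=0.0007,
        n_events=20,
        n_capsids=300,
        flank3_range=(500, 1_200),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return make_genome(small_cfg)
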