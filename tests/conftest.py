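import pytest
from hypothesis import HealthCheck, settings

from msypipe import synthetic
from msypipe.config import ScenarioConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> ScenarioConfig:
    """Reference scenario on a 570 kb chromosome (scale 0.02)."""
    return ScenarioConfig(scale=0.02, seed=7)


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    x, y, truth = synthetic.simulate_xy_pair(small_cfg)
    return small_cfg, x, y, truth


@pytest.fixture(scope="session")
def small_netted(small_scenario):
    from msypipe.divergence import align_chromosomes

    _, x, y, _ = small_scenario
    return align_chromosomes(x, y)
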