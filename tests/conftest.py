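import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180919)


@pytest.fixture
def small_generator_config():
    """Six-channel generator (two channels per area) for cheap pipeline runs."""
    from cholosc.synth import GeneratorConfig

    return GeneratorConfig(n_channels=6,
                           area_map=("DG", "DG", "CA3", "CA3", "CA1", "CA1"))
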