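import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from odkinetics import SimConfig, generate_study

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

TIME_GRID = np.arange(0.0, 181.0, 30.0)


@pytest.fixture(scope="session")
def time_grid():
    return TIME_GRID.copy()


@pytest.fixture()
def default_config():
    return SimConfig(seed=7)


@pytest.fixture()
def noise_free_study():
    cfg = SimConfig(seed=11, m0_sd=0.0, noise_sd_mass=0.0, noise_sd_s=0.0)
    measurements, initial, truth = generate_study(cfg)
    return cfg, measurements, initial, truth
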