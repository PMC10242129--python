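import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """One small coupled simulation shared by connectivity/pipeline tests.

    Two structures x four channels, 60 s on each side of the injection,
    stationary across the step (null drug effect).
    """
    from lfpnet.sim import simulate_experiment
    from lfpnet.study import scaled_study_config

    cfg = scaled_study_config(
        "null", seed=7,
        n_structures=2, channels_per_structure=4,
        duration_pre=60.0, duration_post=60.0,
    )
    rec, emap, truth = simulate_experiment(cfg)
    return cfg, rec, emap, truth
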