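import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Four-participant uniform-parameter M7 cohort with moderate noise."""
    from looprl.synthetic_cohort import recovery_preset, sample_cohort

    return sample_cohort(recovery_preset("M7", 4, seed=3, sigma=8.0))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Two-participant noise-free cohort: trajectories are deterministic."""
    from looprl.synthetic_cohort import recovery_preset, sample_cohort
    import dataclasses

    cfg = dataclasses.replace(recovery_preset("M7", 2, seed=9), sigma=0.0)
    return sample_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
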