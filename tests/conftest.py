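import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from magclass import SimConfig, generate_experiment, preprocess

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with zero trial noise: slopes are exactly recoverable."""
    cfg = SimConfig(
        n_per_group={"A": 3, "B": 3},
        intercept_dist=(500.0, 40.0),
        b_dist_dist=(-12.0, 5.0),
        b_size_dist=(1.5, 2.0),
        noise=(0.0, 0.0, 0.0),
        error_base=0.0,
        anticipation_rate=0.0,
        seed=11,
    )
    trials, truth = generate_experiment(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def realistic_cohort():
    """Calibrated cohort (defaults, emulated study conditions), preprocessed once per session."""
    cfg = SimConfig(seed=20260925 % 2**31)
    trials, truth = generate_experiment(cfg)
    retained, report = preprocess(trials)
    return cfg, trials, truth, retained, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
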