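import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import liftrisk as lr
from liftrisk import pipeline


@pytest.fixture()
def tiny_recording():
    """A 2-second, deterministic 8-channel recording for I/O tests."""
    config = lr.SyntheticConfig(n_participants=1, task_duration=2.0, seed=5)
    return lr.generate_recording(config, "P1", 0,
                                 rng=np.random.default_rng(5))


@pytest.fixture(scope="session")
def default_cohort_table():
    """Feature table of the default synthetic cohort (6 participants,
    400-sample windows, stride 50, fixed seed) shared by the slower tests."""
    config = pipeline.ExperimentConfig(seed=11)
    config.synthetic.seed = 11
    return pipeline.build_feature_table(config)
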