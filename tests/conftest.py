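import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """Small simulated dataset shared by integration-style tests."""
    from speechtrack import synthetic_data as sd

    cfg = sd.SynthConfig(n_subjects=2, n_channels=6, n_lines_per_condition=2,
                         rate=64.0, seed=99)
    dataset, truth = sd.simulate_eeg_dataset(cfg)
    return cfg, dataset, truth
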