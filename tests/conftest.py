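import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_truth():
    """A 60-transcript truth table shared by cheap tests."""
    from tailtop.synthetic import SimulationConfig, simulate_transcriptome

    cfg = SimulationConfig(n_transcripts=60, top_fraction=0.2, excluded_fraction=0.05)
    return simulate_transcriptome(cfg, seed=99)
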