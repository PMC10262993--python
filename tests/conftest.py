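import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trial_spec():
    """Trial audio at a reduced sample rate to keep filtering cheap."""
    from voicecue.stimuli import TrialAudioSpec

    return TrialAudioSpec(sample_rate=16000.0)
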