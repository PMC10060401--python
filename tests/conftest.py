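import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# statsmodels emits convergence chatter on small mixed models; irrelevant here
warnings.filterwarnings("ignore", module="statsmodels")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def standard_lfp():
    """One 5-min simulated trial with ground truth, shared across tests."""
    from swrlab.synthetic import LfpSimConfig, simulate_lfp

    return simulate_lfp(LfpSimConfig(duration=300.0, seed=123))


@pytest.fixture(scope="session")
def behavior_table():
    from swrlab.synthetic import BehaviorSimConfig, simulate_behavior

    return simulate_behavior(BehaviorSimConfig(n_per_group=10, seed=7))


@pytest.fixture()
def sine_trace():
    """Factory for pure-tone traces at 1 kHz sampling."""
    from swrlab.types import LfpTrace

    def make(freq_hz: float, duration: float = 10.0, amp: float = 50.0, fs: float = 1000.0):
        t = np.arange(int(duration * fs)) / fs
        return LfpTrace(samples=amp * np.sin(2 * np.pi * freq_hz * t), sampling_rate=fs)

    return make
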