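import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meanet.types import SpikeTrain

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float,
                  electrode_id: str = "E00") -> SpikeTrain:
    """Independent helper for test fixtures (not the package's simulator)."""
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0, duration_s, n))
    # drop exact duplicates (measure-zero but guard the strictness invariant)
    times = np.unique(times)
    return SpikeTrain(electrode_id, times)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
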