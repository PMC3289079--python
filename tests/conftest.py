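import numpy as np
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


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_hp(rng, n: int) -> str:
    return "".join(rng.choice(["H", "P"], size=n))


def random_folds(rng, m: int) -> np.ndarray:
    return rng.integers(0, 6, size=m, dtype=np.int64)
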