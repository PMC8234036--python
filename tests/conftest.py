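import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def frame_pair():
    """An 8x8 background-50 frame pair where a 2x2 blob of 200 moves right by 2 px."""
    from flockwatch.motion import Frame

    prev = np.full((8, 8), 50, dtype=np.uint8)
    prev[3:5, 2:4] = 200
    cur = np.full((8, 8), 50, dtype=np.uint8)
    cur[3:5, 4:6] = 200
    return Frame(cur, index=1), Frame(prev, index=0)
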