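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
    return np.random.default_rng(2024)


def random_seq(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mask_of(intervals, n):
    """Per-base boolean coverage mask: the independent interval oracle."""
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def mask_components(mask):
    """Connected components of a boolean mask as half-open intervals."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out
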