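import numpy as np
import pytest

from disalign import AlignmentConfig, DisorderCurve


@pytest.fixture
def worked_pair():
    """The 3x2 pair whose alignment is fully known from the brute-force oracle:
    score 0.7, path (1,1),(2,2),(3,2), f_M 0.8 at V_match 0.05."""
    a = DisorderCurve(np.array([0.1, 0.9, 0.2]), id="A")
    b = DisorderCurve(np.array([0.1, 0.2]), id="B")
    return a, b


@pytest.fixture
def unit_segment_config():
    """Default parameters but single-step segments allowed."""
    return AlignmentConfig(min_segment_length=1)


@pytest.fixture
def random_curve_pairs():
    """Factory: n seeded pairs of uniform-random curves with lengths in a range."""

    def make(n_pairs, seed=0, min_len=2, max_len=7):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n_pairs):
            la, lb = rng.integers(min_len, max_len + 1, size=2)
            pairs.append((DisorderCurve(rng.uniform(0, 1, la)),
                          DisorderCurve(rng.uniform(0, 1, lb))))
        return pairs

    return make
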