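import numpy as np
import pytest

from bmdd import CountMatrix, Hyperparams


@pytest.fixture
def small_hp() -> Hyperparams:
    """Three taxa with a near-zero spike and well-separated high modes."""
    return Hyperparams(pi=[0.5, 0.3, 0.7], alpha0=[0.05, 0.05, 0.05], alpha1=[5.0, 2.0, 8.0])


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(11)
    W = rng.multinomial(500, [0.5, 0.2, 0.3], size=6)
    W[0, 1] = 0
    W[0, 0] += 1  # keep totals positive after zeroing
    return CountMatrix(W)
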