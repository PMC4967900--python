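import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160801)


def random_gray_roi(rng, max_side=8, n_levels=32):
    """Random small ROI of gray levels in 1..n_levels (possibly few tones)."""
    rows = int(rng.integers(3, max_side + 1))
    cols = int(rng.integers(3, max_side + 1))
    n_tones = int(rng.integers(1, min(n_levels, 6) + 1))
    tones = rng.choice(np.arange(1, n_levels + 1), size=n_tones, replace=False)
    return rng.choice(tones, size=(rows, cols)).astype(np.int64)
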