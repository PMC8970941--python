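import numpy as np
import pytest

from wedm import TimeSeriesSample
from wedm.segmentation import Segment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def wide_segment():
    """The canonical worked segment: flanks of 100 samples each side."""
    return Segment(1, 201, 101)


@pytest.fixture
def two_target_sample(rng):
    return TimeSeriesSample(rng.standard_normal(100), [30, 60])


def random_annotated_sample(rng, max_n=500, max_targets=8):
    """A random valid sample: sorted unique interior targets."""
    n = int(rng.integers(5, max_n))
    k = int(rng.integers(1, min(max_targets, n - 2) + 1))
    cps = np.sort(rng.choice(np.arange(2, n), size=k, replace=False))
    return TimeSeriesSample(rng.standard_normal(n), cps)
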