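import numpy as np
import pytest

from bamr import RatingsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ratings():
    """Deterministic 4 subjects x 3 raters table."""
    values = np.array(
        [
            [5.0, 5.0, 5.0],
            [0.0, 1.0, 2.0],
            [10.0, 12.0, 11.0],
            [3.0, 4.0, 8.0],
        ]
    )
    return RatingsMatrix(values, subject_ids=("a", "b", "c", "d"))


@pytest.fixture
def two_rater_ratings(rng):
    values = rng.normal(50.0, 5.0, size=(30, 2))
    return RatingsMatrix(values)
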