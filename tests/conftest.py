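import numpy as np
import pytest

from contoursim import (
    entropy_profile,
    make_regular_polygon,
    resample_contour,
)


@pytest.fixture(scope="session")
def square_profile_1000():
    """Normalized entropy profile of a square resampled to 1000 nodes."""
    contour = resample_contour(make_regular_polygon(4, 250), 1000)
    return entropy_profile(contour)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
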