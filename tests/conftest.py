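import warnings

import numpy as np
import pytest

from neuritescope.images import CalibratedImage


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # analysis functions warn on degenerate inputs; tests assert the values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_image(pixels, pixel_size=0.2):
    return CalibratedImage(np.asarray(pixels, dtype=float), pixel_size)
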