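import numpy as np
import pytest

from apicoquant import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A tiny random calibrated movie (T=4, 16x16)."""
    data = rng.uniform(10, 100, size=(4, 16, 16))
    return ImageStack(data=data, pixel_size_um=0.2, frame_interval_s=5.0)


def make_stack(data, pixel_size_um=0.1, frame_interval_s=1.0, z_spacing_um=None):
    return ImageStack(
        data=np.asarray(data),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        z_spacing_um=z_spacing_um,
    )
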