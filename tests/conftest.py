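import numpy as np
import pytest
from hypothesis import settings

from sclsettle.render import ScanProtocol

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_protocol():
    """Compact acquisition protocol for fast rendering in unit tests."""
    return ScanProtocol(
        image_size=(192, 192),
        axial_pitch_um=40.0,
        margin_px=25.0,
        noise_level=0.0,
        support_mm=6.3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
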