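import numpy as np
import pytest

from ringpose.calibration import BoardGeometry
from ringpose.synthetic import simulate_rig


@pytest.fixture(scope="session")
def ring_rig():
    """6 cameras on a ring with mild radial distortion."""
    return simulate_rig(n_cameras=6, radius=120.0, focal=600.0, k1=-0.02)


@pytest.fixture(scope="session")
def clean_rig():
    """Distortion-free 6-camera ring (for exact-recovery checks)."""
    return simulate_rig(n_cameras=6, radius=120.0, focal=600.0, k1=0.0)


@pytest.fixture(scope="session")
def board():
    """6x6-square board, 5 mm squares (matched to the 120 mm rig)."""
    return BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
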