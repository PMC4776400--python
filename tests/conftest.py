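import numpy as np
import pytest

from restdyn.geometry import VolumeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom_iso1():
    """21^3 grid at 1 mm: large enough for a 10 mm sphere around center."""
    return VolumeGeometry((21, 21, 21), (1.0, 1.0, 1.0))


@pytest.fixture
def geom_coarse():
    """12^3 grid at 10 mm: the functional-resolution analysis grid."""
    return VolumeGeometry((12, 12, 12), (10.0, 10.0, 10.0))


@pytest.fixture(autouse=True)
def _quiet_epoch_length_warning():
    """5 s at 208.33 Hz is non-integral by design; silence that one warning."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*non-integral.*", category=UserWarning
        )
        yield
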