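import numpy as np
import pytest

from opticorr.fixtures import default_display_and_cones
from opticorr.spectra import compute_lms_matrix
from opticorr.wavefront import OpticalConfig


@pytest.fixture(scope="session")
def display_cones():
    return default_display_and_cones()


@pytest.fixture(scope="session")
def lms_matrix(display_cones):
    display, cones = display_cones
    return compute_lms_matrix(display, cones)


@pytest.fixture(scope="session")
def coarse_optics():
    """Small, coarsely wavelength-sampled optics for fast PSF tests."""
    return OpticalConfig(
        pupil_diameter_mm=2.0, grid_px=32, field_extent_deg=1.375, wavelength_step_nm=10.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
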