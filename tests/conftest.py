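import numpy as np
import pytest

from hydronirs.calibration import STANDARD_GRID
from hydronirs.chromophores import load_basis
from hydronirs.optics import MeasurementGeometry, build_lut


@pytest.fixture(scope="session")
def geometry():
    return MeasurementGeometry()


@pytest.fixture(scope="session")
def lut(geometry):
    """Default diffusion look-up table, shared across the suite."""
    return build_lut(geometry=geometry, check_interpolation=False)


@pytest.fixture(scope="session")
def basis():
    return load_basis(wavelengths=STANDARD_GRID)


@pytest.fixture(scope="session")
def basis_resolution():
    """Basis convolved to the spectrometer's 7.5 nm resolution."""
    return load_basis(wavelengths=STANDARD_GRID, resolution_fwhm_nm=7.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
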