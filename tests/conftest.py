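import numpy as np
import pytest

from ipdtmon.spectra import Spectrum
from ipdtmon.synthetic import make_basis


@pytest.fixture(scope="session")
def basis():
    return make_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wavelength_grid():
    return np.arange(490.0, 781.0, 0.5)


def make_spectrum(wavelengths, intensities, **meta):
    return Spectrum(np.asarray(wavelengths), np.asarray(intensities), meta=meta)


@pytest.fixture()
def spectrum_factory(wavelength_grid):
    """Build spectra on the session grid from a callable of wavelength."""

    def factory(fn, **meta):
        return make_spectrum(wavelength_grid, fn(wavelength_grid), **meta)

    return factory
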