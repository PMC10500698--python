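import numpy as np
import pytest

from qnmrfit import AcquisitionParams, DistortionSpec, Peak, Signature, simulate_sample


@pytest.fixture
def params():
    """Default acquisition: 10 kHz spectral width, 4096 points, 400 MHz."""
    return AcquisitionParams(
        dwell_time=1e-4, n_points=4096, spectrometer_frequency=400.0, spectral_offset=0.0
    )


@pytest.fixture
def params_large():
    return AcquisitionParams(dwell_time=1e-4, n_points=16384, spectrometer_frequency=400.0)


def make_peak_signature(params, fwhm_points=20.0, shift_ppm=0.0, name="peak", protons=1):
    alpha = fwhm_points * params.frequency_step * np.pi
    return Signature(name, (Peak(shift_ppm, alpha, 1.0),), protons)


@pytest.fixture
def single_peak(params_large):
    """(params, signature, spectrum) of one noiseless unit Lorentzian."""
    sig = make_peak_signature(params_large)
    _, spec = simulate_sample([(sig, 1.0)], DistortionSpec(), params_large)
    return params_large, sig, spec


@pytest.fixture
def misphased_peak(params_large):
    """Same peak carrying a 0.25 rad zero-order phase error."""
    sig = make_peak_signature(params_large)
    _, spec = simulate_sample(
        [(sig, 1.0)], DistortionSpec(phase_error=(0.25, 0.0)), params_large
    )
    return params_large, sig, spec


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
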