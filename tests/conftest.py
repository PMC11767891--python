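import numpy as np
import pytest

from nmlab.core import AcqPars, Fid, Spectrum1D
from nmlab import synthetic


@pytest.fixture
def acq_small():
    return synthetic.default_acq(n_points=2048)


@pytest.fixture
def acq_medium():
    return synthetic.default_acq(n_points=8192)


@pytest.fixture
def mix_fid(acq_medium):
    return synthetic.gen_fid(synthetic.metabolite_mix_peaks(), acq_medium,
                             noise_sd=0.002, seed=1)


@pytest.fixture
def mix_spectrum(mix_fid):
    from nmlab import spec1d
    return spec1d.fourier_transform(spec1d.apodize_exponential(mix_fid, 0.3))


def make_flat_spectrum(values, high_ppm=10.0, low_ppm=0.0):
    """Build a Spectrum1D directly from a real array (descending ppm axis)."""
    values = np.asarray(values, dtype=float)
    axis = np.linspace(high_ppm, low_ppm, values.size)
    return Spectrum1D(points=values.astype(np.complex128), ppm_axis=axis)


@pytest.fixture
def flat_spectrum_factory():
    return make_flat_spectrum
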