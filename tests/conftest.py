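import numpy as np
import pytest

from rldeconv import NoiseSpec, PhantomSpec, forward_model, make_gaussian_psf, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_psf_7():
    """Odd-sized isotropic Gaussian PSF, unit sum."""
    return make_gaussian_psf((7, 7, 7), (1.5, 1.5, 1.5))


@pytest.fixture
def bead_scene():
    """Seeded bead phantom with its PSF and noisy measured image."""
    spec = PhantomSpec(shape=(48, 48, 48), kind="beads", count=8, size=3.0,
                       intensity=100.0, seed=7)
    truth = make_phantom(spec)
    psf = make_gaussian_psf((9, 9, 9), (2.0, 1.5, 1.5))
    measured = forward_model(truth, psf,
                             NoiseSpec(model="poisson", photon_scale=1.0, seed=7))
    return truth, psf, measured
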