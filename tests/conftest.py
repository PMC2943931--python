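import numpy as np
import pytest

from covmap.dynamics import RSNDynamics
from covmap.spectra import SpectralEpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_spectra(rng):
    """Tiny normalized-flag-off spectral set: 7 epochs, 4 channels, 3 bins."""
    return SpectralEpochSet(
        amplitudes=rng.standard_normal((7, 4, 3)),
        bin_freqs=np.array([2.0, 4.0, 6.0]),
    )


@pytest.fixture
def small_dynamics(rng):
    """Tiny dynamics: 2 RSNs x 7 volumes."""
    return RSNDynamics(rng.standard_normal((2, 7)), tr=1.98)
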