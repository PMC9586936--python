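import numpy as np
import pytest

from flimcoreg import synthetic as syn
from flimcoreg.hypercube import FlimHypercube


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def texture64():
    """Histology-like RGB texture, 64 px, reused across registration tests."""
    return syn.make_texture(64, seed=1, n_blobs=60, blob_radius=(3, 8), blur_sigma=1.5)


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale two-region phantom: (cube, tau_map, pseudo_histology)."""
    spec = syn.PhantomSpec(size=32, n_bands=4, seed=7)
    return syn.make_phantom(spec)


def make_cube(counts, bin_ns=0.4, wavelengths=None):
    counts = np.asarray(counts)
    S = counts.shape[2]
    if wavelengths is None:
        wavelengths = np.linspace(500, 780, S)
    return FlimHypercube(counts=counts, wavelengths=wavelengths, time_bin_ns=bin_ns)
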