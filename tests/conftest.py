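import numpy as np
import pytest

from hyperleaf.cube_io import HyperspectralCube, WavelengthAxis
from hyperleaf.synthleaf import simulate_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_axis():
    return WavelengthAxis.uniform(400.0, 1000.0, 16)


@pytest.fixture
def random_cube(rng, small_axis):
    data = rng.uniform(0.0, 1.0, size=(6, 5, len(small_axis))).astype(np.float32)
    return HyperspectralCube(data, small_axis)


@pytest.fixture(scope="session")
def separable_spectra():
    """Well-separated six-class mean spectra on the working 761-band axis."""
    X, y, axis = simulate_spectra(40, seed=11)
    return X, y, axis
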