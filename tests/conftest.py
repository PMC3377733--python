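import numpy as np
import pytest

from ramanmix import SpectralLibrary, Spectrum, fit_pca, generate_library
from ramanmix.simulate import default_analyte_config, default_background_config


@pytest.fixture
def axis():
    return np.linspace(400.0, 1800.0, 60)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_libraries():
    """Small default-shaped synthetic analyte/background libraries."""
    analyte = generate_library(default_analyte_config(n_spectra=12, seed=11))
    background = generate_library(default_background_config(n_spectra=16, seed=12))
    return analyte, background


@pytest.fixture
def small_models(small_libraries):
    analyte, background = small_libraries
    return fit_pca(analyte, 5), fit_pca(background, 5)


def make_orthonormal_rows(rng: np.random.Generator, p: int, length: int) -> np.ndarray:
    """Random orthonormal rows (for hand-built PCA models in tests)."""
    q, _ = np.linalg.qr(rng.normal(size=(length, p)))
    return q.T


@pytest.fixture
def orthonormal_rows():
    return make_orthonormal_rows
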