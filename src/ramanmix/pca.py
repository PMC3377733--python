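"""Per-compound variability models from calibration libraries.

Each compound (analyte or background) is characterised by the mean of its
calibration spectra together with the leading principal components and
eigenvalues of the sample covariance. The eigenvalue of component p equals
the sample variance (denominator N-1) of the projections of the centred
calibration spectra onto that component; it sets the statistically
plausible scale of that mode of variation and is what the HLP penalty
divides by.

Numerical conventions
---------------------
* Eigenvalues below ``ZERO_EIGENVALUE_RTOL`` times the largest eigenvalue
  are treated as exactly zero, and the model is truncated to the numerical
  rank (``truncated`` flag set) — only components with non-zero eigenvalues
  carry information.
* Component sign is fixed by making each component's largest-magnitude
  element positive, so fitted models are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectralLibrary, ValidationError

__all__ = ["PCAModel", "fit_pca", "project", "ZERO_EIGENVALUE_RTOL"]

ZERO_EIGENVALUE_RTOL = 1e-12

DEFAULT_N_COMPONENTS = 5


@dataclass(frozen=True)
class PCAModel:
    """Mean spectrum, orthonormal principal components and eigenvalues.

    Attributes
    ----------
    axis : (L,) array
        Shared wavenumber axis of the calibration set.
    mean : (L,) array
        Arithmetic mean of the calibration spectra.
    components : (P, L) array
        Orthonormal principal components, one per row, ordered by
        nonincreasing eigenvalue.
    eigenvalues : (P,) array
        Sample variance (ddof=1) of the calibration spectra's projections
        onto each component.
    n_samples : int
        Number of calibration spectra the model was fitted to.
    truncated : bool
        True when fewer numerically non-zero components existed than were
        requested.
    """

    axis: np.ndarray
    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    n_samples: int
    truncated: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_points(self) -> int:
        return self.mean.size

    def mean_spectrum(self, label: str | None = None) -> Spectrum:
        return Spectrum(self.axis, self.mean, label=label)


def fit_pca(library: SpectralLibrary, n_components: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Fit a :class:`PCAModel` to a calibration library.

    Parameters
    ----------
    library : SpectralLibrary
        N >= 2 replicate spectra of one compound.
    n_components : int
        Number of principal components requested; must satisfy
        ``1 <= n_components <= min(N-1, L)``. If the library's numerical
        rank is lower, the returned model is truncated to that rank (with a
        warning and ``truncated=True``).
    """
    N, L = library.spectra.shape
    if N < 2:
        raise ValidationError("PCA needs at least 2 calibration spectra")
    max_p = min(N - 1, L)
    if not 1 <= n_components <= max_p:
        raise ValueError(
            f"n_components={n_components} out of range [1, {max_p}] for N={N}, L={L}"
        )
    mean = library.spectra.mean(axis=0)
    centered = library.spectra - mean
    # SVD of centred data: eigenvalue_p = s_p^2 / (N-1), the sample variance
    # of the projections onto component p.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (N - 1)

    # Absolute floor guards against floating-point dust (e.g. a library of
    # identical spectra leaves ~eps-sized residue after mean subtraction).
    eps = np.finfo(float).eps
    floor = (eps * max(1.0, float(np.abs(library.spectra).max())) * np.sqrt(L)) ** 2 * N
    if eigenvalues.size and eigenvalues[0] > floor:
        nonzero = eigenvalues > ZERO_EIGENVALUE_RTOL * eigenvalues[0]
    else:
        nonzero = np.zeros_like(eigenvalues, dtype=bool)
    rank = int(nonzero.sum())
    truncated = rank < n_components
    if truncated:
        warnings.warn(
            f"calibration set has numerical rank {rank} < requested "
            f"{n_components} components; model truncated",
            stacklevel=2,
        )
    keep = min(n_components, rank)
    components = vt[:keep]
    eigenvalues = eigenvalues[:keep]

    # Deterministic sign: largest-magnitude element of each component positive.
    if keep:
        flip = np.sign(components[np.arange(keep), np.abs(components).argmax(axis=1)])
        flip[flip == 0] = 1.0
        components = components * flip[:, None]

    return PCAModel(
        axis=library.axis,
        mean=mean,
        components=components,
        eigenvalues=eigenvalues,
        n_samples=N,
        truncated=truncated,
    )


def project(model: PCAModel, spectrum: Spectrum | np.ndarray) -> np.ndarray:
    """Coordinates of a spectrum in the model's principal-component basis.

    Returns the dot products of (spectrum - mean) with each component row.
    """
    x = spectrum.intensities if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if x.shape != model.mean.shape:
        raise ValueError(
            f"spectrum length {x.size} does not match model length {model.mean.size}"
        )
    return model.components @ (x - model.mean)
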