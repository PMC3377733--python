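"""Hybrid linear analysis (HLA): background-orthogonal calibration vector.

HLA estimates an analyte concentration as a single dot product between a
calibration vector b and the measured spectrum. The calibration vector is
the part of the analyte reference spectrum S_A that cannot be explained by
the background's principal components: project S_A onto each background
component, subtract the projections to leave a residual r, and normalise.
By construction b annihilates every background variation mode in the
calibration span, so the estimate is immune to background variability that
the components capture — but, unlike HLP, it models no variability in the
analyte spectrum itself and ignores the eigenvalues.

Normalisation: b = r / (r . S_A), so b . S_A = 1 and the dot product reads
out the weight directly in units of the reference. Since S_A - r lies in
the component span and r is orthogonal to it, r . S_A = r . r, so this is
algebraically the same as dividing by r . r.

The measured spectrum has the mean background subtracted before the dot
product: the component span is annihilated by construction, but the mean
background is not in that span and would otherwise contribute a constant
offset b . mean_bg to every estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import UnmixingResults
from .pca import PCAModel
from .spectra import Spectrum

__all__ = [
    "CalibrationVector",
    "DegenerateCalibrationError",
    "hla_calibrate",
    "hla_estimate",
    "HybridLinearAnalysis",
    "HLAResults",
]


class DegenerateCalibrationError(ValueError):
    """The analyte reference lies (numerically) inside the background span."""


@dataclass(frozen=True)
class CalibrationVector:
    """HLA calibration vector with its provenance.

    ``b`` satisfies b . S_A = 1 and is orthogonal to every background
    principal component. ``residual_norm`` is ||r|| and ``analyte_overlap``
    is r . S_A, the normalisation denominator.
    """

    axis: np.ndarray
    b: np.ndarray
    residual_norm: float
    analyte_overlap: float
    n_background_components: int


def hla_calibrate(background: PCAModel, analyte_ref: Spectrum) -> CalibrationVector:
    """Build the HLA calibration vector from a background model and analyte reference.

    r = S_A - sum_p (S_A . V_p) V_p over the background components V_p,
    then b = r / (r . S_A). Raises :class:`DegenerateCalibrationError` when
    the analyte reference is numerically inside the background span
    (r . S_A <= 1e-12 ||S_A||^2), in which case no calibration vector can
    separate analyte from background.
    """
    s_a = analyte_ref.intensities
    if s_a.shape != background.mean.shape:
        raise ValueError("analyte reference is not on the background model's axis")
    V = background.components  # (P, L), orthonormal rows
    if V.shape[0]:
        r = s_a - V.T @ (V @ s_a)
    else:
        r = s_a.copy()
    overlap = float(r @ s_a)
    if overlap <= 1e-12 * float(s_a @ s_a):
        raise DegenerateCalibrationError(
            "analyte reference lies within the background principal-component "
            "span; HLA calibration is impossible"
        )
    return CalibrationVector(
        axis=background.axis,
        b=r / overlap,
        residual_norm=float(np.linalg.norm(r)),
        analyte_overlap=overlap,
        n_background_components=V.shape[0],
    )


def hla_estimate(
    measured: Spectrum,
    calib: CalibrationVector,
    ref_concentration: float = 1.0,
    background_mean: Spectrum | np.ndarray | None = None,
) -> tuple[float, float]:
    """Estimate (concentration, raw weight) of the analyte in a measured spectrum.

    weight = b . (measured - mean background); concentration = weight *
    ref_concentration, where ``ref_concentration`` is the concentration at
    which the analyte reference was measured.
    """
    m = measured.intensities
    if m.shape != calib.b.shape:
        raise ValueError("measured spectrum is not on the calibration axis")
    if background_mean is not None:
        mean = (
            background_mean.intensities
            if isinstance(background_mean, Spectrum)
            else np.asarray(background_mean, float)
        )
        if mean.shape != m.shape:
            raise ValueError("background mean is not on the calibration axis")
        m = m - mean
    weight = float(calib.b @ m)
    return weight * ref_concentration, weight


class HLAResults(UnmixingResults):
    """HLA estimate with a reconstructed fit for residual diagnostics.

    HLA itself only produces the dot-product weight; for residual-based
    diagnostics the fitted spectrum is reconstructed as the analyte
    contribution plus the best background explanation: mean background plus
    the projection of (measured - w S_A - mean) onto the background
    component span. The residual is then the part of the measurement that
    neither the analyte reference nor the background model can explain.
    """

    def __init__(
        self,
        measured: Spectrum,
        background: PCAModel,
        analyte_ref: Spectrum,
        calib: CalibrationVector,
        ref_concentration: float = 1.0,
    ) -> None:
        self.method = "HLA"
        self.measured = measured
        self.calibration = calib
        self.background = background
        concentration, weight = hla_estimate(
            measured, calib, ref_concentration, background_mean=background.mean
        )
        self.weights = np.array([weight])
        self.concentration_estimate = concentration
        self.ref_concentration = ref_concentration

        remainder = measured.intensities - weight * analyte_ref.intensities - background.mean
        V = background.components
        bg_flex = V.T @ (V @ remainder) if V.shape[0] else np.zeros_like(remainder)
        self.fitted = weight * analyte_ref.intensities + background.mean + bg_flex
        self.residual = measured.intensities - self.fitted
        self.diagnostics = {"n_background_components": calib.n_background_components}


class HybridLinearAnalysis:
    """HLA unmixing model.

    Parameters
    ----------
    measured : Spectrum
        Mixture spectrum to analyse.
    background : PCAModel
        Variability model of the background calibration set.
    analyte_ref : Spectrum
        Analyte reference spectrum (typically the mean of the analyte
        calibration set), measured at ``ref_concentration``.
    ref_concentration : float, default 1.0
        Concentration of the solution the reference was measured from.
    """

    def __init__(
        self,
        measured: Spectrum,
        background: PCAModel,
        analyte_ref: Spectrum,
        ref_concentration: float = 1.0,
    ) -> None:
        self.measured = measured
        self.background = background
        self.analyte_ref = analyte_ref
        self.ref_concentration = ref_concentration
        self.calibration = hla_calibrate(background, analyte_ref)

    def fit(self) -> HLAResults:
        return HLAResults(
            self.measured,
            self.background,
            self.analyte_ref,
            self.calibration,
            self.ref_concentration,
        )
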