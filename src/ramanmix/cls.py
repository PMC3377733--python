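"""Classical least squares unmixing with polynomial background (LS-qP).

The measured spectrum is modelled as a linear combination of K reference
spectra, optionally augmented with the q+1 basis polynomials of a q-th
order polynomial that absorbs slowly varying background drift (LS-3P for
q=3, the standard choice for Raman data). Weights are the minimum-norm
least-squares solution obtained through the Moore-Penrose pseudoinverse.

The polynomial block uses Chebyshev polynomials on the wavenumber axis
rescaled affinely to [-1, 1]: raw powers of wavenumbers ~10^3 would make
the design matrix catastrophically ill-conditioned, and the model itself
only requires *some* basis of the degree-q polynomial space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev

from .base import UnmixingResults
from .spectra import Spectrum

__all__ = [
    "DesignMatrix",
    "build_design",
    "cls_fit",
    "ClassicalLeastSquares",
    "CLSResults",
    "PINV_RCOND",
]

# Relative singular-value cutoff for rank decisions in the pseudoinverse.
PINV_RCOND = 1e-12


@dataclass(frozen=True)
class DesignMatrix:
    """Reference spectra plus optional polynomial columns, ready to fit.

    ``column_roles`` tags each column as a reference (its label) or a
    polynomial degree (``"poly:d"``).
    """

    axis: np.ndarray
    columns: np.ndarray  # (L, K') with K' = K + (q+1) when polynomial enabled
    column_roles: tuple[str, ...]
    n_references: int
    poly_order: int
    collinear: bool = False

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def build_design(references: list[Spectrum], poly_order: int = 3) -> DesignMatrix:
    """Assemble the L x K' design matrix for :func:`cls_fit`.

    Parameters
    ----------
    references : list of Spectrum
        Reference spectra sharing one axis (analyte references and, for
        LS-qP, an average background spectrum).
    poly_order : int
        Order q of the polynomial background block (q+1 columns);
        ``poly_order=-1`` disables the block.
    """
    if not references:
        raise ValueError("need at least one reference spectrum")
    axis = references[0].axis
    for ref in references[1:]:
        if ref.axis.shape != axis.shape or not np.array_equal(ref.axis, axis):
            raise ValueError("reference spectra do not share a common axis")
    if poly_order < -1:
        raise ValueError("poly_order must be >= -1")

    cols = [ref.intensities for ref in references]
    roles = [ref.label or f"ref{i}" for i, ref in enumerate(references)]
    if poly_order >= 0:
        # Degree-d Chebyshev basis on the axis mapped affinely onto [-1, 1].
        t = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
        basis = chebyshev.chebvander(t, poly_order)  # (L, q+1)
        cols.extend(basis.T)
        roles.extend(f"poly:{d}" for d in range(poly_order + 1))

    columns = np.column_stack(cols)
    if not np.all(np.isfinite(columns)):
        raise ValueError("design matrix contains non-finite values")
    norms = np.linalg.norm(columns, axis=0)
    if np.any(norms == 0):
        raise ValueError("design matrix contains an all-zero column")
    collinear = np.linalg.matrix_rank(columns, tol=None) < columns.shape[1]
    return DesignMatrix(
        axis=axis,
        columns=columns,
        column_roles=tuple(roles),
        n_references=len(references),
        poly_order=poly_order,
        collinear=bool(collinear),
    )


class CLSResults(UnmixingResults):
    """Weights, polynomial coefficients and diagnostics of an LS-qP fit."""

    def __init__(
        self,
        measured: Spectrum,
        design: DesignMatrix,
        solution: np.ndarray,
    ) -> None:
        self.method = f"LS-{design.poly_order}P" if design.poly_order >= 0 else "CLS"
        self.measured = measured
        self.design = design
        K = design.n_references
        self.weights = solution[:K]
        self.poly_coeffs = solution[K:]
        self.solution = solution
        self.fitted = design.columns @ solution
        self.residual = measured.intensities - self.fitted
        self.diagnostics = {"collinear": design.collinear}

    def _summary_rows(self):
        rows = super()._summary_rows()
        for d, c in enumerate(self.poly_coeffs):
            rows.append((f"Poly coeff[{d}]", f"{c: .6g}"))
        if self.design.collinear:
            rows.append(("Warning", "design matrix is rank deficient (collinear columns)"))
        return rows


def cls_fit(measured: Spectrum, design: DesignMatrix) -> CLSResults:
    """Minimum-norm least-squares unmixing of ``measured`` against ``design``.

    Solves W = pinv(S) m, where pinv is the Moore-Penrose pseudoinverse with
    relative singular-value cutoff :data:`PINV_RCOND`. Negative weights are
    reported as-is; their sign carries physical information.
    """
    m = measured.intensities
    if m.size != design.columns.shape[0]:
        raise ValueError(
            f"measured length {m.size} does not match design rows {design.columns.shape[0]}"
        )
    solution = np.linalg.pinv(design.columns, rcond=PINV_RCOND) @ m
    return CLSResults(measured, design, solution)


class ClassicalLeastSquares:
    """Classical least squares unmixing model (LS-qP).

    Parameters
    ----------
    measured : Spectrum
        The mixture spectrum to unmix.
    references : list of Spectrum
        Pure-compound reference spectra (analyte(s) and average background).
    poly_order : int, default 3
        Order of the polynomial background block; -1 disables it.

    Examples
    --------
    >>> model = ClassicalLeastSquares(measured, [analyte_ref, background_ref])
    >>> res = model.fit()
    >>> res.weights, res.durbin_watson  # doctest: +SKIP
    """

    def __init__(self, measured: Spectrum, references: list[Spectrum], poly_order: int = 3):
        self.measured = measured
        self.design = build_design(references, poly_order=poly_order)

    def fit(self) -> CLSResults:
        return cls_fit(self.measured, self.design)
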