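"""Hybrid least squares / PCA unmixing (HLP).

HLP extends classical least squares by letting every reference spectrum
flex along the principal components of its own calibration set, with the
amount of flex constrained by the PCA eigenvalues. The signal model is

    x = sum_k w_k ( mean_k + sum_p c_pk Z_pk )

where mean_k and Z_pk come from compound k's :class:`~ramanmix.pca.PCAModel`
and the c_pk are per-spectrum flex coefficients. Under a Gaussian noise
model with standard deviation sigma and independent zero-mean Gaussian
priors c_pk ~ N(0, lambda_pk), maximising the log-posterior is equivalent
to minimising the penalized least-squares cost

    J(W, C) = ||m - x||^2 + beta * sum_k sum_p c_pk^2 / lambda_pk

with hyperparameter beta = sigma^2 (overridable). The penalty keeps the
reference-spectrum deviations within the statistically plausible range
observed during calibration — the eigenvalue information that HLA throws
away.

The cost is minimised by block-coordinate descent from a zero initial
guess: with C fixed, the effective references are formed and W is the
minimum-norm pseudoinverse solution (a plain least-squares step, so the
first iteration starts from the CLS-on-means solution); with W fixed, the
C update is a Tikhonov-regularised least squares problem

    C = (A^T A + Gamma)^-1 A^T Q,   Gamma = diag(beta / lambda_pk),

where Q = m - sum_k w_k mean_k and the column of A indexed by (p, k) is
w_k Z_pk. Each half-step minimises the cost exactly over its block, so the
cost trace is nonincreasing; iteration stops when the largest relative
weight change drops below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import UnmixingResults
from .pca import PCAModel, ZERO_EIGENVALUE_RTOL
from .spectra import Spectrum, SpectralLibrary

__all__ = [
    "HLPConfig",
    "HLPResults",
    "estimate_sigma",
    "hlp_fit",
    "weight_to_concentration",
    "HybridLSPCA",
]


@dataclass(frozen=True)
class HLPConfig:
    """Solver configuration for :func:`hlp_fit`.

    Parameters
    ----------
    sigma : float
        Standard deviation of the (Gaussian, wavelength-independent) noise
        in the measured signal, in intensity units; estimate it from
        replicate measurements with :func:`estimate_sigma`. Must be > 0.
    n_components : int or sequence of int, default 5
        Number of principal components used per compound (a scalar applies
        to all compounds). Components beyond a model's numerical rank are
        ignored. Estimates are insensitive to this count once it exceeds
        three or four.
    max_iter : int, default 500
        Iteration cap for the alternating solver; convergence is typically
        reached within ~100 iterations.
    tol : float, default 1e-8
        Relative weight-change convergence threshold.
    beta_override : float, optional
        Replaces sigma^2 as the penalty hyperparameter beta. beta -> 0
        removes the penalty; beta -> infinity pins all flex coefficients to
        zero, recovering CLS on the mean spectra.
    """

    sigma: float = 1.0
    n_components: int | tuple[int, ...] = 5
    max_iter: int = 500
    tol: float = 1e-8
    beta_override: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0 (estimate it from replicates)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.beta_override is not None and self.beta_override < 0:
            raise ValueError("beta_override must be >= 0")

    @property
    def beta(self) -> float:
        return self.sigma**2 if self.beta_override is None else self.beta_override


def estimate_sigma(replicates: SpectralLibrary) -> float:
    """Noise standard deviation from repeated measurements of one static target.

    Returns sqrt of the mean (over wavenumbers) of the per-wavenumber sample
    variance (ddof=1) across replicates. A value of 0 (identical
    replicates) is returned as-is but cannot be used to run HLP.
    """
    if replicates.n_spectra < 2:
        raise ValueError("need at least 2 replicate spectra to estimate sigma")
    per_wavelength_var = replicates.spectra.var(axis=0, ddof=1)
    return float(np.sqrt(per_wavelength_var.mean()))


def weight_to_concentration(weight: float, ref_concentration: float) -> float:
    """Convert a fitted weight into a concentration.

    The weight is a dimensionless multiple of the reference spectrum, so
    concentration = weight * ref_concentration, with ``ref_concentration``
    the concentration of the solution the reference spectrum was measured
    from (0.8 nM for the nanoparticle stock used as the running example).
    """
    if ref_concentration <= 0:
        raise ValueError("ref_concentration must be positive")
    return weight * ref_concentration


class HLPResults(UnmixingResults):
    """Weights, flex coefficients and convergence diagnostics of an HLP fit."""

    def __init__(
        self,
        measured: Spectrum,
        models: list[PCAModel],
        config: HLPConfig,
        weights: np.ndarray,
        coeffs: list[np.ndarray],
        iterations: int,
        converged: bool,
        cost_trace: np.ndarray,
    ) -> None:
        self.method = "HLP"
        self.measured = measured
        self.models = models
        self.config = config
        self.weights = weights
        self.coeffs = coeffs
        self.iterations = iterations
        self.converged = converged
        self.cost_trace = cost_trace
        self.effective_references = [
            mdl.mean + (mdl.components[: c.size].T @ c if c.size else 0.0)
            for mdl, c in zip(models, coeffs)
        ]
        self.fitted = np.sum(
            [w * ref for w, ref in zip(weights, self.effective_references)], axis=0
        )
        self.residual = measured.intensities - self.fitted
        self.diagnostics = {
            "iterations": iterations,
            "converged": converged,
            "beta": config.beta,
            "monotone_cost": bool(np.all(np.diff(cost_trace) <= 1e-9 * max(cost_trace[0], 1.0))),
        }

    @property
    def coeff_matrix(self) -> np.ndarray:
        """Flex coefficients as a (P_max, K) matrix, zero-padded per compound."""
        P = max((c.size for c in self.coeffs), default=0)
        out = np.zeros((P, len(self.coeffs)))
        for k, c in enumerate(self.coeffs):
            out[: c.size, k] = c
        return out

    def _summary_rows(self):
        rows = super()._summary_rows()
        rows.append(("Iterations", f"{self.iterations} ({'converged' if self.converged else 'NOT converged'})"))
        rows.append(("Penalty beta", f"{self.config.beta:.6g}"))
        rows.append(("Final cost", f"{self.cost_trace[-1]:.6g}"))
        return rows


def hlp_fit(measured: Spectrum, models: list[PCAModel], config: HLPConfig) -> HLPResults:
    """Fit the HLP model by alternating least-squares / Tikhonov descent.

    Parameters
    ----------
    measured : Spectrum
        Mixture spectrum on the models' shared axis.
    models : list of PCAModel
        One variability model per compound (analyte(s) and background).
    config : HLPConfig
        Noise level, component counts and solver controls.

    Returns
    -------
    HLPResults
        Weights w_k, per-compound flex coefficients, the reconstructed
        effective reference spectra, the fitted spectrum and residual, and
        the (nonincreasing) penalized cost trace.
    """
    m = measured.intensities
    K = len(models)
    if K < 1:
        raise ValueError("need at least one PCA model")
    L = models[0].mean.size
    for mdl in models:
        if mdl.mean.size != L or not np.array_equal(mdl.axis, models[0].axis):
            raise ValueError("all PCA models must share one wavenumber axis")
    if m.size != L:
        raise ValueError("measured spectrum is not on the models' axis")

    n_comp = config.n_components
    if np.isscalar(n_comp):
        n_comp = (int(n_comp),) * K
    elif len(n_comp) != K:
        raise ValueError("n_components sequence length must equal the number of models")

    means = np.column_stack([mdl.mean for mdl in models])  # (L, K)
    # Per compound: components with numerically non-zero eigenvalues only;
    # a zero eigenvalue means an infinite penalty, i.e. the coefficient is
    # pinned to zero, so the component is simply excluded.
    Z: list[np.ndarray] = []
    lam: list[np.ndarray] = []
    for mdl, p in zip(models, n_comp):
        p_use = min(int(p), mdl.n_components)
        ev = mdl.eigenvalues[:p_use]
        if ev.size and ev[0] > 0:
            keep = ev > ZERO_EIGENVALUE_RTOL * ev[0]
        else:
            keep = np.zeros(ev.size, dtype=bool)
        Z.append(mdl.components[:p_use][keep])
        lam.append(ev[keep])

    beta = config.beta
    P_total = sum(z.shape[0] for z in Z)
    gamma = beta / np.concatenate(lam) if P_total else np.empty(0)
    Z_stack = np.vstack(Z) if P_total else np.empty((0, L))  # rows: (k, p) blocks
    block = np.repeat(np.arange(K), [z.shape[0] for z in Z])  # compound of each row

    W = np.zeros(K)
    C = np.zeros(P_total)

    def split_coeffs(c: np.ndarray) -> list[np.ndarray]:
        return [c[block == k] for k in range(K)]

    def cost(W: np.ndarray, C: np.ndarray) -> float:
        eff = means + (Z_stack.T * C) @ _block_matrix if P_total else means
        x = eff @ W
        pen = float(C @ (gamma * C)) if P_total else 0.0
        return float(np.sum((m - x) ** 2)) + pen

    # Indicator mapping stacked (k,p) rows to compounds, used to assemble
    # the effective references sum_p c_pk Z_pk without Python loops.
    _block_matrix = np.zeros((P_total, K))
    if P_total:
        _block_matrix[np.arange(P_total), block] = 1.0

    cost_trace = [cost(W, C)]
    iterations = 0
    converged = False
    for iterations in range(1, config.max_iter + 1):
        # W-step: effective references with C fixed, minimum-norm pseudoinverse.
        eff = means + (Z_stack.T * C) @ _block_matrix if P_total else means
        W_new = np.linalg.pinv(eff, rcond=1e-12) @ m

        # C-step: Tikhonov-regularised solve with W fixed.
        if P_total and np.any(W_new):
            Q = m - means @ W_new
            A = Z_stack.T * W_new[block]  # column (k,p) = w_k Z_pk
            AtA = A.T @ A
            AtA[np.diag_indices_from(AtA)] += gamma
            C = np.linalg.solve(AtA, A.T @ Q)
        # else: all weights zero -> design matrix is zero, skip the C-step.

        cost_trace.append(cost(W_new, C))
        delta = np.max(np.abs(W_new - W) / np.maximum(np.abs(W_new), 1e-12)) if K else 0.0
        W = W_new
        if delta < config.tol:
            converged = True
            break

    return HLPResults(
        measured=measured,
        models=models,
        config=config,
        weights=W,
        coeffs=split_coeffs(C),
        iterations=iterations,
        converged=converged,
        cost_trace=np.asarray(cost_trace),
    )


class HybridLSPCA:
    """HLP unmixing model (statsmodels-style front end to :func:`hlp_fit`).

    Parameters
    ----------
    measured : Spectrum
        Mixture spectrum to unmix.
    models : list of PCAModel
        Per-compound variability models sharing the measured axis.
    sigma : float
        Measurement noise standard deviation (see :func:`estimate_sigma`).
    **config_kwargs
        Remaining :class:`HLPConfig` fields (n_components, max_iter, tol,
        beta_override).
    """

    def __init__(
        self,
        measured: Spectrum,
        models: list[PCAModel],
        sigma: float = 1.0,
        **config_kwargs,
    ) -> None:
        self.measured = measured
        self.models = list(models)
        self.config = HLPConfig(sigma=sigma, **config_kwargs)

    def fit(self) -> HLPResults:
        return hlp_fit(self.measured, self.models, self.config)
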