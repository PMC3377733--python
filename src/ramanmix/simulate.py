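"""Synthetic spectral libraries and the factorial simulation study.

The generator emulates the variability seen in real calibration scans of a
nanoparticle solution and a paraffin-like background: each synthetic
spectrum is a sum of Gaussian peaks whose amplitudes and centre positions
jitter from sample to sample, plus (for backgrounds) a broad baseline bump
near 1600-1800 cm^-1 whose amplitude varies strongly between samples, plus
additive i.i.d. Gaussian noise. Everything is driven by one seed, so
libraries are bit-reproducible.

The factorial study mirrors the characterisation protocol used to compare
the unmixing methods: pick one analyte spectrum i and one background
spectrum j from their libraries, simulate m = v * analyte_i + background_j
for every weight v in a halving sequence (2^0 ... 2^-13 by default; the
background is not weighted), and recover v with each method calibrated on
leave-one-out statistics — the analyte model is fitted to all analyte
spectra except i and the background model to all background spectra except
j, so the analysed spectra never inform their own calibration.
Leave-one-out models are cached per excluded index (N_a + N_b PCA fits,
not N_a * N_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cls import build_design, cls_fit
from .hla import HLAResults, hla_calibrate
from .hlp import HLPConfig, hlp_fit
from .metrics import EvaluationRecord, dw_histogram, fractional_error
from .pca import PCAModel, fit_pca
from .spectra import Spectrum, SpectralLibrary

__all__ = [
    "GeneratorConfig",
    "StudyConfig",
    "StudyResult",
    "default_analyte_config",
    "default_background_config",
    "generate_library",
    "run_factorial_study",
    "summarize_study",
    "DEFAULT_WEIGHT_LEVELS",
]

#: The halving weight sequence 2^0 ... 2^-13 (14 levels).
DEFAULT_WEIGHT_LEVELS: tuple[float, ...] = tuple(2.0**-i for i in range(14))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic spectrum generator.

    Attributes
    ----------
    axis_range : (float, float)
        Wavenumber range in cm^-1.
    n_points : int
        Number of wavenumber samples L.
    peaks : tuple of (center, width, amplitude)
        Gaussian peaks of the base spectrum (cm^-1, cm^-1, intensity).
    amplitude_jitter : float
        Relative standard deviation of per-peak amplitude variation.
    shift_jitter : float
        Standard deviation of per-peak centre shifts, cm^-1.
    baseline : (center, width, amplitude, amplitude_std) or None
        Broad variable bump added to every spectrum (the paraffin-style
        baseline feature); its amplitude is drawn per spectrum.
    noise_sigma : float
        Standard deviation of additive i.i.d. Gaussian noise.
    n_spectra : int
        Number of spectra to generate.
    seed : int
        Seed of the generator's private random stream.
    """

    axis_range: tuple[float, float] = (400.0, 1800.0)
    n_points: int = 700
    peaks: tuple[tuple[float, float, float], ...] = ()
    amplitude_jitter: float = 0.05
    shift_jitter: float = 1.0
    baseline: tuple[float, float, float, float] | None = None
    noise_sigma: float = 0.01
    n_spectra: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.amplitude_jitter < 0 or self.shift_jitter < 0 or self.noise_sigma < 0:
            raise ValueError("jitter and noise standard deviations must be >= 0")
        for c, w, a in self.peaks:
            if w <= 0:
                raise ValueError(f"peak at {c} cm^-1 has non-positive width {w}")
        if self.baseline is not None and self.baseline[3] < 0:
            raise ValueError("baseline amplitude_std must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_range[0], self.axis_range[1], self.n_points)


# Default analyte: several narrow Raman-style peaks, like a nanoparticle
# reporter spectrum. Default background: fewer, paraffin-like bands (narrow
# enough that their variation defeats a low-order polynomial) plus the
# strongly variable broad bump in the 1600-1800 cm^-1 region.
_ANALYTE_PEAKS = (
    (520.0, 9.0, 0.55),
    (655.0, 8.0, 0.80),
    (795.0, 12.0, 0.45),
    (935.0, 10.0, 1.00),
    (1085.0, 9.0, 0.65),
    (1215.0, 11.0, 0.90),
    (1355.0, 10.0, 0.50),
    (1585.0, 13.0, 0.70),
)
_BACKGROUND_PEAKS = (
    (460.0, 22.0, 0.45),
    (890.0, 16.0, 0.60),
    (1063.0, 14.0, 0.70),
    (1296.0, 18.0, 0.80),
    (1441.0, 20.0, 0.65),
)
_BACKGROUND_BUMP = (1700.0, 80.0, 0.50, 0.20)


def default_analyte_config(n_spectra: int = 106, seed: int = 0) -> GeneratorConfig:
    """Generator settings emulating an analyte (nanoparticle) calibration scan."""
    return GeneratorConfig(peaks=_ANALYTE_PEAKS, n_spectra=n_spectra, seed=seed)


def default_background_config(n_spectra: int = 476, seed: int = 1) -> GeneratorConfig:
    """Generator settings emulating a paraffin-style background scan."""
    return GeneratorConfig(
        peaks=_BACKGROUND_PEAKS,
        baseline=_BACKGROUND_BUMP,
        n_spectra=n_spectra,
        seed=seed,
    )


def generate_library(config: GeneratorConfig) -> SpectralLibrary:
    """Draw a synthetic calibration library (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    axis = config.axis
    n, L = config.n_spectra, axis.size
    peaks = config.peaks
    spectra = np.zeros((n, L))
    for i in range(n):
        y = np.zeros(L)
        for center, width, amplitude in peaks:
            amp = amplitude * (1.0 + rng.normal(0.0, config.amplitude_jitter))
            c = center + rng.normal(0.0, config.shift_jitter)
            y += amp * np.exp(-0.5 * ((axis - c) / width) ** 2)
        if config.baseline is not None:
            bc, bw, ba, bstd = config.baseline
            amp = rng.normal(ba, bstd)
            y += amp * np.exp(-0.5 * ((axis - bc) / bw) ** 2)
        if config.noise_sigma > 0:
            y += rng.normal(0.0, config.noise_sigma, size=L)
        spectra[i] = y
    return SpectralLibrary(axis, spectra, labels=tuple(f"synthetic{i}" for i in range(n)))


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the factorial simulation study.

    Attributes
    ----------
    analyte_library, background_library : SpectralLibrary
        Calibration libraries on one shared axis.
    weight_levels : tuple of float
        Strictly decreasing positive analyte weights (default 2^0..2^-13).
    n_components : int
        Principal components per compound model.
    ref_concentration : float
        Concentration (nM) of the solution the analyte reference was
        measured from; weights are converted to concentrations with it.
    methods : tuple of str
        Subset of {"LS-3P", "HLA", "HLP"}.
    sigma : float
        Noise standard deviation handed to HLP (beta = sigma^2).
    subsample : (int, int), optional
        Cap on (n_analyte, n_background) spectra for desk-scale runs; the
        subset is drawn deterministically from ``seed``.
    seed : int
        Seed for subsampling (the study itself is deterministic).
    """

    analyte_library: SpectralLibrary
    background_library: SpectralLibrary
    weight_levels: tuple[float, ...] = DEFAULT_WEIGHT_LEVELS
    n_components: int = 5
    ref_concentration: float = 0.8
    methods: tuple[str, ...] = ("LS-3P", "HLA", "HLP")
    sigma: float = 0.01
    subsample: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        levels = np.asarray(self.weight_levels, float)
        if levels.size == 0 or np.any(levels <= 0) or np.any(np.diff(levels) >= 0):
            raise ValueError("weight_levels must be strictly decreasing and positive")
        unknown = set(self.methods) - {"LS-3P", "HLA", "HLP"}
        if not self.methods or unknown:
            raise ValueError(f"methods must be a nonempty subset of LS-3P/HLA/HLP, got {unknown}")
        if not np.array_equal(self.analyte_library.axis, self.background_library.axis):
            raise ValueError("analyte and background libraries must share one axis")


@dataclass
class StudyResult:
    """Outcome of a factorial study: per-spectrum records and aggregates."""

    records: list[EvaluationRecord]
    n_combinations: int
    weight_levels: tuple[float, ...]
    methods: tuple[str, ...]
    hlp_converged: int = 0
    hlp_monotone: int = 0
    hlp_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def summaries(self) -> pd.DataFrame:
        return summarize_study(self)

    @property
    def dw_histograms(self) -> pd.DataFrame:
        return dw_histogram([r for r in self.records if np.isfinite(r.durbin_watson)])

    def plot_fractional_errors(self, ax=None):
        """Mean +/- std fractional error vs true weight, one line per method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        summ = self.summaries
        for method, grp in summ.groupby("method"):
            ax.errorbar(
                grp["true_weight"], grp["mean_fractional_error"],
                yerr=grp["std_fractional_error"], label=method, capsize=2,
            )
        ax.set_xscale("log", base=2)
        ax.set_xlabel("true analyte weight")
        ax.set_ylabel("fractional error")
        ax.legend()
        return ax


def _loo_models(
    library: SpectralLibrary, indices: np.ndarray, n_components: int
) -> dict[int, PCAModel]:
    """Leave-one-out PCA models, one per excluded index (cached up front)."""
    n_comp = min(n_components, library.n_spectra - 2, library.n_points)
    return {int(i): fit_pca(library.exclude(int(i)), n_comp) for i in indices}


def _subsample_indices(n: int, cap: int | None, rng: np.random.Generator) -> np.ndarray:
    if cap is None or cap >= n:
        return np.arange(n)
    return np.sort(rng.choice(n, size=cap, replace=False))


def _safe_dw(residual: np.ndarray) -> float:
    from .metrics import durbin_watson

    try:
        return durbin_watson(residual)
    except ValueError:
        return float("nan")


def run_factorial_study(config: StudyConfig, count_only: bool = False) -> StudyResult:
    """Run the leave-one-out factorial study over (weight, analyte, background).

    For every combination the simulated measurement is
    ``v * analyte_i + background_j``; each requested method estimates v
    (converted to a concentration via ``ref_concentration``) and its
    fractional error and residual Durbin-Watson statistic are recorded.

    With ``count_only=True`` only the combination bookkeeping is done — no
    models are fitted — which is useful to verify the size of a planned
    grid (e.g. 14 levels x 106 analyte x 476 background = 706,384).
    """
    a_lib, b_lib = config.analyte_library, config.background_library
    if a_lib.n_spectra < 2 or b_lib.n_spectra < 2:
        raise ValueError("leave-one-out calibration needs at least 2 spectra per library")

    rng = np.random.default_rng(config.seed)
    n_a_cap, n_b_cap = config.subsample if config.subsample else (None, None)
    a_idx = _subsample_indices(a_lib.n_spectra, n_a_cap, rng)
    b_idx = _subsample_indices(b_lib.n_spectra, n_b_cap, rng)
    levels = tuple(float(v) for v in config.weight_levels)
    n_combinations = len(levels) * a_idx.size * b_idx.size

    result = StudyResult(
        records=[],
        n_combinations=n_combinations,
        weight_levels=levels,
        methods=config.methods,
    )
    if count_only:
        return result

    axis = a_lib.axis
    a_models = _loo_models(a_lib, a_idx, config.n_components)
    b_models = _loo_models(b_lib, b_idx, config.n_components)
    ref_c = config.ref_concentration
    hlp_config = HLPConfig(sigma=config.sigma, n_components=config.n_components)

    for i in a_idx:
        i = int(i)
        analyte_i = a_lib.spectra[i]
        model_a = a_models[i]
        mean_a = Spectrum(axis, model_a.mean, label="analyte-mean")
        for j in b_idx:
            j = int(j)
            model_b = b_models[j]
            mean_b = Spectrum(axis, model_b.mean, label="background-mean")
            mixture_base = b_lib.spectra[j]

            if "LS-3P" in config.methods:
                design = build_design([mean_a, mean_b], poly_order=3)
            if "HLA" in config.methods:
                calib = hla_calibrate(model_b, mean_a)

            for v in levels:
                measured = Spectrum(axis, v * analyte_i + mixture_base)
                true_conc = v * ref_c

                if "LS-3P" in config.methods:
                    res = cls_fit(measured, design)
                    est = res.weights[0] * ref_c
                    result.records.append(
                        EvaluationRecord(
                            "LS-3P", v, float(res.weights[0]),
                            fractional_error(est, true_conc), _safe_dw(res.residual),
                        )
                    )
                if "HLA" in config.methods:
                    res = HLAResults(measured, model_b, mean_a, calib, ref_c)
                    result.records.append(
                        EvaluationRecord(
                            "HLA", v, float(res.weights[0]),
                            fractional_error(res.concentration_estimate, true_conc),
                            _safe_dw(res.residual),
                        )
                    )
                if "HLP" in config.methods:
                    res = hlp_fit(measured, [model_a, model_b], hlp_config)
                    est = res.weights[0] * ref_c
                    result.hlp_total += 1
                    result.hlp_converged += int(res.converged)
                    result.hlp_monotone += int(res.diagnostics["monotone_cost"])
                    result.records.append(
                        EvaluationRecord(
                            "HLP", v, float(res.weights[0]),
                            fractional_error(est, true_conc), _safe_dw(res.residual),
                        )
                    )
    return result


def summarize_study(result: StudyResult) -> pd.DataFrame:
    """Per (method, weight level) mean/std of fractional error.

    Standard deviations use denominator n-1; a level with a single record
    reports std 0 and is flagged by its n column.
    """
    if not result.records:
        raise ValueError("study produced no records")
    frame = pd.DataFrame([r.__dict__ for r in result.records])
    grouped = frame.groupby(["method", "true_weight"], sort=False)
    summ = grouped["fractional_error"].agg(
        mean_fractional_error="mean",
        std_fractional_error=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
        mean_abs_fractional_error=lambda s: s.abs().mean(),
        n="count",
    )
    dw = grouped["durbin_watson"].mean().rename("mean_durbin_watson")
    out = pd.concat([summ, dw], axis=1).reset_index()
    return out.sort_values(["method", "true_weight"], ascending=[True, False]).reset_index(
        drop=True
    )
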