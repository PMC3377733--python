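"""Goodness-of-fit and accuracy statistics.

Two metrics are used throughout the evaluation of the unmixing methods:

* the Durbin-Watson statistic of the fit residual, DW = sum_i (e_i -
  e_{i-1})^2 / sum_i e_i^2 with the residual ordered by ascending
  wavenumber. DW lies in [0, 4]; 2 means no serial correlation between
  successive residuals, values well below 2 mean positive serial
  correlation (structured, poorly fitted residuals), values above 2 mean
  negative serial correlation;
* the signed fractional error of a concentration estimate,
  (estimated - true) / true.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

__all__ = [
    "EvaluationRecord",
    "durbin_watson",
    "fractional_error",
    "dw_histogram",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """One (method, simulated spectrum) evaluation outcome."""

    method: str
    true_weight: float
    estimated_weight: float
    fractional_error: float
    durbin_watson: float


def durbin_watson(residual: np.ndarray) -> float:
    """Durbin-Watson statistic of a residual vector.

    Successive differences are taken over ascending wavenumber index. The
    statistic is undefined for an all-zero residual (perfect fit) and for
    vectors shorter than 2.
    """
    e = np.asarray(residual, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("residual must be a 1-D vector of length >= 2")
    if not np.any(e) or np.sum(e * e) == 0.0:
        # the second clause catches subnormal residuals whose squares underflow
        raise ValueError("Durbin-Watson statistic is undefined for an all-zero residual")
    return float(_sm_durbin_watson(e))


def fractional_error(estimated: float, true: float) -> float:
    """Signed relative deviation (estimated - true) / true; true must be nonzero."""
    if true == 0:
        raise ValueError("fractional error is undefined for a true concentration of 0")
    return (estimated - true) / true


def dw_histogram(records: list[EvaluationRecord], bins: int = 40) -> pd.DataFrame:
    """Per-method histogram of Durbin-Watson statistics over [0, 4].

    Returns a DataFrame with columns ``bin_left``, ``bin_right`` and one
    count column per method; bin edges are identical across methods so the
    histograms superimpose.
    """
    if not records:
        raise ValueError("no evaluation records given")
    edges = np.linspace(0.0, 4.0, bins + 1)
    out = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:]})
    for method in sorted({r.method for r in records}):
        values = [r.durbin_watson for r in records if r.method == method]
        counts, _ = np.histogram(values, bins=edges)
        out[method] = counts
    return out
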