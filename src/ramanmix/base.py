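"""Shared Results machinery for the unmixing estimators."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from typing import Any

import numpy as np

from . import metrics
from .spectra import Spectrum

__all__ = ["UnmixingResults"]


def _jsonify(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    if is_dataclass(value) and not isinstance(value, type):
        return _jsonify(asdict(value))
    return value


class UnmixingResults:
    """Base class for fit results of the unmixing models.

    Subclasses set ``method``, ``weights``, ``fitted`` and ``residual``
    (with ``measured == fitted + residual``) plus method-specific fields.
    """

    method: str
    measured: Spectrum
    weights: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray

    @property
    def durbin_watson(self) -> float:
        """Durbin-Watson statistic of the residual (serial-correlation diagnostic)."""
        return metrics.durbin_watson(self.residual)

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residual))

    def concentration(self, ref_concentration: float, component: int = 0) -> float:
        """Convert a fitted weight to a concentration.

        The weight is a dimensionless multiple of the reference spectrum, so
        the concentration is ``weight * ref_concentration`` where
        ``ref_concentration`` is the concentration at which the reference
        was measured.
        """
        if ref_concentration <= 0:
            raise ValueError("ref_concentration must be positive")
        return float(self.weights[component]) * ref_concentration

    def _summary_rows(self) -> list[tuple[str, str]]:
        rows = [("Method", self.method), ("Wavenumber points", str(self.fitted.size))]
        for k, w in enumerate(np.atleast_1d(self.weights)):
            rows.append((f"Weight[{k}]", f"{w: .6g}"))
        try:
            dw = f"{self.durbin_watson:.4f}"
        except ValueError:
            dw = "undefined (zero residual)"
        rows.append(("Residual norm", f"{self.residual_norm:.6g}"))
        rows.append(("Durbin-Watson", dw))
        return rows

    def summary(self) -> str:
        rows = self._summary_rows()
        width = max(len(k) for k, _ in rows)
        title = f"{self.method} unmixing results"
        lines = [title, "=" * len(title)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def to_document(self) -> dict:
        """Structured key-value tree with arrays (JSON-serialisable)."""
        doc = {
            "method": self.method,
            "weights": _jsonify(np.atleast_1d(self.weights)),
            "fitted": _jsonify(self.fitted),
            "residual": _jsonify(self.residual),
            "axis": _jsonify(self.measured.axis),
            "residual_norm": self.residual_norm,
        }
        try:
            doc["durbin_watson"] = self.durbin_watson
        except ValueError:
            doc["durbin_watson"] = None
        return doc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonify(self.to_document()), fh, indent=1)

    def plot(self, ax=None):
        """Plot measured vs fitted spectrum with the residual underneath."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.measured.axis, self.measured.intensities, label="measured", lw=0.8)
        ax.plot(self.measured.axis, self.fitted, label=f"{self.method} fit", lw=0.8)
        ax.plot(self.measured.axis, self.residual, label="residual", lw=0.8)
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax
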