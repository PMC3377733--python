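"""Containers and I/O for Raman spectra.

A :class:`Spectrum` is a wavenumber axis paired with an intensity vector; a
:class:`SpectralLibrary` is a stack of replicate spectra sharing one axis
(the calibration-set container used throughout the package). Axes are in
wavenumbers (cm^-1) and must be strictly increasing; intensities are in
arbitrary detector units.

File formats are plain delimited text: either a single matrix file (first
column the wavenumber axis, one column per spectrum, one header row of
labels) or a directory of two-column wavenumber/intensity files. Mismatched
axes across files are an error — silent interpolation would corrupt
calibration statistics, so resampling is always an explicit call to
:func:`resample`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "SpectraError",
    "ParseError",
    "ValidationError",
    "AxisMismatchError",
    "read_library",
    "write_library",
    "resample",
]


class SpectraError(ValueError):
    """Base class for spectral data errors."""


class ParseError(SpectraError):
    """A cell of a spectral text file could not be parsed."""


class ValidationError(SpectraError):
    """A spectrum or library violates a structural invariant."""


class AxisMismatchError(SpectraError):
    """Two spectra expected to share an axis do not."""


def _validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 1:
        raise ValidationError("axis must be a non-empty 1-D vector")
    if not np.all(np.isfinite(axis)):
        raise ValidationError("axis contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        raise ValidationError("axis must be strictly increasing")
    return axis


@dataclass(frozen=True)
class Spectrum:
    """A single measured or synthetic spectrum.

    Parameters
    ----------
    axis : array-like
        Wavenumbers in cm^-1, strictly increasing, length >= 2.
    intensities : array-like
        Detector intensities, same length as ``axis``, all finite.
    label : str, optional
        Free-text identifier (e.g. the source file or pixel).
    """

    axis: np.ndarray
    intensities: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        axis = _validate_axis(self.axis)
        inten = np.asarray(self.intensities, dtype=float)
        if inten.shape != axis.shape:
            raise ValidationError(
                f"axis (length {axis.size}) and intensities (length {inten.size}) differ"
            )
        if not np.all(np.isfinite(inten)):
            raise ValidationError("intensities contain non-finite values")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.axis.size


@dataclass(frozen=True)
class SpectralLibrary:
    """A calibration set: N replicate spectra on one shared axis.

    ``spectra`` is an (N, L) matrix with one spectrum per row.
    """

    axis: np.ndarray
    spectra: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        axis = _validate_axis(self.axis)
        mat = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if mat.shape[0] < 1 or mat.shape[1] != axis.size:
            raise ValidationError(
                f"spectra matrix {mat.shape} incompatible with axis length {axis.size}"
            )
        if not np.all(np.isfinite(mat)):
            raise ValidationError("library contains non-finite intensities")
        labels = self.labels
        if labels is not None:
            labels = tuple(str(x) for x in labels)
            if len(labels) != mat.shape[0]:
                raise ValidationError("number of labels does not match number of spectra")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "spectra", mat)
        object.__setattr__(self, "labels", labels)

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_points(self) -> int:
        return self.spectra.shape[1]

    def __len__(self) -> int:
        return self.n_spectra

    def __getitem__(self, i: int) -> Spectrum:
        label = self.labels[i] if self.labels is not None else None
        return Spectrum(self.axis, self.spectra[i], label=label)

    def mean_spectrum(self, label: str = "mean") -> Spectrum:
        return Spectrum(self.axis, self.spectra.mean(axis=0), label=label)

    def exclude(self, index: int) -> "SpectralLibrary":
        """Library with row ``index`` removed (leave-one-out calibration)."""
        keep = np.arange(self.n_spectra) != index
        labels = None
        if self.labels is not None:
            labels = tuple(l for l, k in zip(self.labels, keep) if k)
        return SpectralLibrary(self.axis, self.spectra[keep], labels=labels)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectralLibrary":
        if not spectra:
            raise ValidationError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis.shape != axis.shape or not np.allclose(s.axis, axis, rtol=0, atol=0):
                raise AxisMismatchError("spectra do not share a common wavenumber axis")
        labels = tuple(s.label or f"s{i}" for i, s in enumerate(spectra))
        return cls(axis, np.vstack([s.intensities for s in spectra]), labels=labels)


_DELIMITERS = (",", "\t", ";")


def _sniff_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    return best if counts[best] > 0 else ","


def _read_matrix(path: Path) -> SpectralLibrary:
    text = path.read_text()
    delim = _sniff_delimiter(text.splitlines()[0] if text else "")
    try:
        frame = pd.read_csv(io.StringIO(text), sep=delim, header=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse delimited matrix: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need a wavenumber column plus at least one spectrum column")
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce")
        if bad.isna().any():
            row = int(bad.isna().idxmax())
            raise ParseError(f"{path}: non-numeric cell at data row {row}, column {col!r}")
        frame[col] = bad
    axis = frame.iloc[:, 0].to_numpy(dtype=float)
    mat = frame.iloc[:, 1:].to_numpy(dtype=float).T
    labels = tuple(str(c) for c in frame.columns[1:])
    return SpectralLibrary(axis, mat, labels=labels)


def _read_two_column(path: Path) -> Spectrum:
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    delim = _sniff_delimiter(first)
    frame = pd.read_csv(io.StringIO(text), sep=delim, header=None, comment="#")
    if frame.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns, found {frame.shape[1]}")
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce")
        if bad.isna().any():
            row = int(bad.isna().idxmax())
            raise ParseError(f"{path}: non-numeric cell at data row {row}, column {col}")
    return Spectrum(
        frame.iloc[:, 0].to_numpy(dtype=float),
        frame.iloc[:, 1].to_numpy(dtype=float),
        label=path.stem,
    )


def read_library(path: str | os.PathLike, dialect: str = "matrix") -> SpectralLibrary:
    """Read a calibration library from delimited text.

    Parameters
    ----------
    path : path-like
        With ``dialect="matrix"``, a single delimited file whose first
        column is the wavenumber axis and whose remaining columns are
        spectra (one header row of labels). With ``dialect="per-file"``, a
        directory of two-column wavenumber/intensity files; files are taken
        in sorted name order and must share an identical axis.
    dialect : {"matrix", "per-file"}

    Raises
    ------
    ParseError, ValidationError, AxisMismatchError
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if dialect == "matrix":
        return _read_matrix(p)
    if dialect == "per-file":
        if not p.is_dir():
            raise ParseError(f"{p}: per-file dialect expects a directory")
        files = sorted(f for f in p.iterdir() if f.is_file())
        if not files:
            raise ParseError(f"{p}: directory contains no spectrum files")
        spectra = [_read_two_column(f) for f in files]
        axis = spectra[0].axis
        for s, f in zip(spectra[1:], files[1:]):
            if s.axis.shape != axis.shape or not np.array_equal(s.axis, axis):
                raise AxisMismatchError(
                    f"{f}: wavenumber axis differs from {files[0]} "
                    "(no silent resampling; call resample explicitly)"
                )
        return SpectralLibrary.from_spectra(spectra)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_library(library: SpectralLibrary, path: str | os.PathLike) -> None:
    """Write a library as a comma-delimited matrix (inverse of ``read_library``)."""
    labels = library.labels or tuple(f"s{i}" for i in range(library.n_spectra))
    frame = pd.DataFrame(library.spectra.T, columns=list(labels))
    frame.insert(0, "wavenumber", library.axis)
    frame.to_csv(path, index=False, float_format="%.12g")


def resample(spectrum: Spectrum, target_axis: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_axis``.

    Extrapolation is refused: every target wavenumber must lie within the
    spectrum's axis range.
    """
    target = np.asarray(target_axis, dtype=float)
    lo, hi = spectrum.axis[0], spectrum.axis[-1]
    if target.min() < lo or target.max() > hi:
        raise ValueError(
            f"target axis [{target.min()}, {target.max()}] extends beyond "
            f"the spectrum range [{lo}, {hi}]; extrapolation is not supported"
        )
    new = np.interp(target, spectrum.axis, spectrum.intensities)
    return Spectrum(target, new, label=spectrum.label)
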