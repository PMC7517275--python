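"""Core data containers for diffuse reflectance spectra.

A :class:`Spectrum` is a single intensity vector on a shared wavelength
grid; a :class:`SpectraSet` holds a whole experiment as an
``n_spectra x n_wavelengths`` matrix with per-row tissue labels and a
hierarchical metadata table (specimen / sample / point / measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed class order used everywhere (confusion matrices, priors, reports).
CLASS_ORDER: tuple[str, ...] = ("fat", "skin", "nerve", "bone", "muscle")

#: Metadata columns carried for every spectrum.
META_COLUMNS: tuple[str, ...] = (
    "spectrum_id",
    "tissue",
    "specimen_id",
    "sample_id",
    "point_idx",
    "measurement_idx",
)


def default_grid(start: float = 220.0, stop: float = 1100.0, step: float = 0.5) -> np.ndarray:
    """Wavelength grid in nm, inclusive of both endpoints (1761 points by default)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return grid


@dataclass
class Spectrum:
    """One intensity vector aligned to a wavelength grid."""

    grid: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = validate_grid(self.grid)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity length {self.intensity.size} does not match "
                f"grid length {self.grid.size}"
            )

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.intensity.copy(), dict(self.meta))


@dataclass
class SpectraSet:
    """A stack of spectra on one grid, with labels and metadata.

    ``matrix`` is ``(n_spectra, n_wavelengths)``; ``labels`` gives the tissue
    class of each row and ``meta`` is a DataFrame with one row per spectrum
    (columns in :data:`META_COLUMNS`).  ``steps`` records the preprocessing
    stages already applied.
    """

    grid: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    steps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = validate_grid(self.grid)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.grid.size:
            raise ValueError("matrix must be (n_spectra, n_wavelengths)")
        if self.labels.size != self.matrix.shape[0]:
            raise ValueError("labels length must equal number of spectra")
        unknown = set(np.unique(self.labels)) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown tissue labels: {sorted(unknown)}")
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError("meta must have one row per spectrum")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i], self.meta.iloc[i].to_dict())

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.grid,
            self.matrix.copy(),
            self.labels.copy(),
            self.meta.copy(),
            list(self.steps),
        )
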