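"""Spectral preprocessing: reflectance, normalization, detrend, smoothing, alignment.

The chain mirrors standard chemometric practice for reflectance spectra:

1. reflectance against a diffuse reference standard with background
   subtraction,
2. per-spectrum normalization to zero mean and unit standard deviation,
3. removal of a least-squares straight line (linear detrend) to suppress
   instrument or orientation drift, optionally followed by re-scaling the
   residual back to unit standard deviation,
4. Savitzky-Golay smoothing, which preserves band positions and widths,
5. icoshift-style segment alignment against the set mean to undo small
   wavelength-calibration shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import Spectrum, SpectraSet

__all__ = [
    "PreprocessConfig",
    "compute_reflectance",
    "normalize",
    "detrend",
    "detrend_deviation",
    "savitzky_golay",
    "align",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_window`` is in grid points (11 points = 5.5 nm on the default
    grid).  ``align_segments`` splits the grid into that many contiguous
    segments which are shifted independently; ``align_max_shift`` bounds
    the per-segment integer lag in grid steps (10 steps = 5 nm).
    """

    sg_window: int = 11
    sg_polyorder: int = 3
    align_segments: int = 1
    align_max_shift: int = 10
    renormalize_after_detrend: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.align_max_shift < 0:
            raise ValueError("align_max_shift must be >= 0")
        if self.align_segments < 1:
            raise ValueError("align_segments must be >= 1")


def compute_reflectance(
    sample: Spectrum,
    reference: Spectrum,
    background: Spectrum,
    tolerance: float = 1e-12,
) -> Spectrum:
    """Reflectance R = (S - B) / (Ref - B) on a shared grid.

    Wavelengths where the reference barely exceeds the background
    (``|Ref - B| < tolerance``) carry no signal; they are set to NaN and
    flagged in ``meta['invalid_mask']`` so downstream stages can exclude
    them.
    """
    for other in (reference, background):
        if other.grid.shape != sample.grid.shape or not np.allclose(
            other.grid, sample.grid
        ):
            raise ValueError("sample, reference and background must share one grid")
    denom = reference.intensity - background.intensity
    invalid = np.abs(denom) < tolerance
    refl = np.full_like(denom, np.nan)
    np.divide(sample.intensity - background.intensity, denom, out=refl, where=~invalid)
    meta = dict(sample.meta)
    meta["invalid_mask"] = invalid
    return Spectrum(sample.grid, refl, meta)


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero variance: constant spectrum cannot be normalized")
    return (matrix - mean) / sd


def normalize(spectrum: Spectrum) -> Spectrum:
    """Zero mean, unit sample standard deviation (n-1 denominator)."""
    if spectrum.intensity.size < 2:
        raise ValueError("normalization needs at least 2 points")
    out = _normalize_rows(spectrum.intensity[None, :])[0]
    return Spectrum(spectrum.grid, out, dict(spectrum.meta))


def _line_fit(grid: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Least-squares straight line per row, evaluated on the grid."""
    x = grid - grid.mean()
    sxx = float(x @ x)
    slope = (matrix @ x) / sxx
    intercept = matrix.mean(axis=1)
    return intercept[:, None] + slope[:, None] * x[None, :]


def detrend(spectrum: Spectrum) -> Spectrum:
    """Subtract the least-squares straight line in wavelength."""
    if spectrum.intensity.size < 3:
        raise ValueError("detrend needs at least 3 points")
    line = _line_fit(spectrum.grid, spectrum.intensity[None, :])[0]
    return Spectrum(spectrum.grid, spectrum.intensity - line, dict(spectrum.meta))


def detrend_deviation(spectrum: Spectrum) -> float:
    """Mean absolute deviation of a spectrum from its own least-squares line.

    This is the scalar summary used to quantify how much linear trend
    remains in a spectrum (zero for an exact straight line).
    """
    line = _line_fit(spectrum.grid, spectrum.intensity[None, :])[0]
    return float(np.mean(np.abs(spectrum.intensity - line)))


def savitzky_golay(spectrum: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Any input that is globally a polynomial of degree <= ``polyorder`` is
    reproduced exactly, including at the edges, where a polynomial is fit
    to the terminal window.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    out = savgol_filter(spectrum.intensity, window, polyorder, mode="interp")
    return Spectrum(spectrum.grid, out, dict(spectrum.meta))


def _shift_rows(row: np.ndarray, lag: int) -> np.ndarray:
    """Shift one segment by ``lag`` steps with edge replication."""
    if lag == 0:
        return row
    out = np.empty_like(row)
    if lag > 0:
        out[lag:] = row[:-lag]
        out[:lag] = row[0]
    else:
        out[:lag] = row[-lag:]
        out[lag:] = row[-1]
    return out


def align(
    spectra: SpectraSet,
    config: PreprocessConfig | None = None,
    reference: np.ndarray | None = None,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Icoshift-style alignment of every spectrum to a reference.

    The grid is split into ``align_segments`` contiguous segments.  For
    each spectrum and segment, the integer lag (|lag| <= align_max_shift)
    maximizing the cross-correlation with the reference's segment is found
    and the segment is shifted by that lag, replicating edge values.  The
    reference defaults to the set mean.  Returns the aligned set and a
    per-spectrum, per-segment lag table.
    """
    if config is None:
        config = PreprocessConfig()
    if len(spectra) == 0:
        raise ValueError("cannot align an empty set")
    n, d = spectra.matrix.shape
    bounds = np.linspace(0, d, config.align_segments + 1).astype(int)
    seg_len = np.diff(bounds).min()
    if config.align_max_shift >= seg_len:
        raise ValueError("align_max_shift must be smaller than the segment length")

    if reference is None:
        reference = spectra.matrix.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (d,):
        raise ValueError("reference length must match the grid")
    out = spectra.matrix.copy()
    lags = np.zeros((n, config.align_segments), dtype=int)
    max_shift = config.align_max_shift
    # ordered by |lag| so exact score ties resolve to the smallest shift
    candidate_lags = np.argsort(np.abs(np.arange(-max_shift, max_shift + 1)),
                                kind="stable") - max_shift

    for s in range(config.align_segments):
        lo, hi = bounds[s], bounds[s + 1]
        seg = hi - lo
        ref_seg = reference[lo:hi]
        # edge-replicated pad; the segment shifted by lag is a contiguous view
        padded = np.pad(out[:, lo:hi], ((0, 0), (max_shift, max_shift)), mode="edge")
        # cosine-normalized correlation: replicated edges cannot inflate the
        # score, so an in-register spectrum always prefers lag 0
        scores = np.empty((n, candidate_lags.size))
        for j, lag in enumerate(candidate_lags):
            window = padded[:, max_shift - lag : max_shift - lag + seg]
            norms = np.linalg.norm(window, axis=1)
            scores[:, j] = (window @ ref_seg) / np.where(norms > 0, norms, 1.0)
        best = candidate_lags[np.argmax(scores, axis=1)]
        lags[:, s] = best
        for i in np.nonzero(best)[0]:
            lag = int(best[i])
            out[i, lo:hi] = padded[i, max_shift - lag : max_shift - lag + seg]

    lag_table = pd.DataFrame(
        lags, columns=[f"segment_{s}" for s in range(config.align_segments)]
    )
    lag_table.insert(0, "spectrum_id", spectra.meta["spectrum_id"].to_numpy())
    aligned = SpectraSet(
        spectra.grid, out, spectra.labels, spectra.meta.copy(),
        steps=spectra.steps + ["align"],
    )
    return aligned, lag_table


def preprocess_pipeline(
    spectra: SpectraSet,
    config: PreprocessConfig | None = None,
) -> SpectraSet:
    """Full chain: normalize -> detrend -> (renormalize) -> smooth -> align.

    Applied per spectrum (vectorized over the whole matrix); alignment is
    the only cross-spectrum stage.  The applied steps are recorded in the
    output's ``steps`` attribute.
    """
    if config is None:
        config = PreprocessConfig()
    matrix = _normalize_rows(spectra.matrix)
    steps = spectra.steps + ["normalize"]

    line = _line_fit(spectra.grid, matrix)
    matrix = matrix - line
    steps.append("detrend")

    if config.renormalize_after_detrend:
        sd = matrix.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero variance after detrend")
        matrix = matrix / sd
        steps.append("renormalize")

    matrix = savgol_filter(matrix, config.sg_window, config.sg_polyorder,
                           axis=1, mode="interp")
    steps.append("savitzky_golay")

    working = SpectraSet(spectra.grid, matrix, spectra.labels, spectra.meta.copy(),
                         steps=steps)
    aligned, _ = align(working, config)
    return aligned
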