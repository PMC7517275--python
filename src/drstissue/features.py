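"""Characteristic spectral points, gradient features and ANOVA-F ranking.

Nine landmarks are located per spectrum — hemoglobin minima at 410, 540
and 575 nm, the maxima between them, and derivative zero crossings in the
lipid/water region (934, 958 nm and the 940-970 nm water valley) plus one
at 436 nm.  The slope of the line joining every ordered pair of landmarks
is a feature: 9 x 9 = 81 gradients per spectrum (the zero diagonal is kept
so the count matches the full ordered-pair matrix).  Features are then
ranked by the one-way ANOVA F ratio (Snedecor F) across tissue classes and
the top-k (default 14) retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Spectrum, SpectraSet

__all__ = [
    "CharacteristicPointSpec",
    "CharacteristicPoints",
    "FeatureMatrix",
    "FRanking",
    "default_point_specs",
    "detect_points",
    "gradients",
    "gradient_feature_matrix",
    "anova_f",
    "select_top_k",
]


@dataclass(frozen=True)
class CharacteristicPointSpec:
    """One landmark: search mode, window and (for derivative zeros) nominal position."""

    index: int
    mode: str  # "minimum" | "maximum" | "derivative_zero"
    window: tuple[float, float]  # nm
    nominal: float | None = None  # nm, for derivative_zero tie-breaking
    compound: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("minimum", "maximum", "derivative_zero"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be (low, high) with low < high")


def default_point_specs(vicinity: float = 10.0) -> list[CharacteristicPointSpec]:
    """The nine standard landmarks.

    Single-wavelength entries get a search window of nominal +/- ``vicinity``
    nm; the 940-970 nm derivative zero is anchored at the 970 nm water
    valley.
    """
    def around(x: float) -> tuple[float, float]:
        return (x - vicinity, x + vicinity)

    return [
        CharacteristicPointSpec(1, "minimum", around(410.0), 410.0, "hemoglobin"),
        CharacteristicPointSpec(2, "maximum", (450.0, 540.0), None, "hemoglobin"),
        CharacteristicPointSpec(3, "minimum", around(540.0), 540.0, "hemoglobin"),
        CharacteristicPointSpec(4, "maximum", (545.0, 570.0), None, "hemoglobin"),
        CharacteristicPointSpec(5, "minimum", around(575.0), 575.0, "hemoglobin"),
        CharacteristicPointSpec(6, "derivative_zero", (940.0, 970.0), 970.0, "water"),
        CharacteristicPointSpec(7, "derivative_zero", around(436.0), 436.0, "hemoglobin"),
        CharacteristicPointSpec(8, "derivative_zero", around(934.0), 934.0, "water"),
        CharacteristicPointSpec(9, "derivative_zero", around(958.0), 958.0, "water"),
    ]


@dataclass
class CharacteristicPoints:
    """Detected landmarks of one spectrum."""

    wavelength: np.ndarray  # nm, length 9
    value: np.ndarray  # intensity at the landmark, length 9
    found: np.ndarray  # bool, False when the fallback path was used

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass
class FeatureMatrix:
    """n_spectra x n_features table with labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.labels.size != self.values.shape[0]:
            raise ValueError("labels length must match row count")

    def select(self, indices: np.ndarray | list[int]) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            self.values[:, indices],
            [self.feature_names[i] for i in indices],
            self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame["label"] = self.labels
        return frame


@dataclass
class FRanking:
    """Per-feature one-way ANOVA F values and the descending order."""

    f_values: np.ndarray
    order: np.ndarray  # feature indices, descending F, ties by smaller index
    feature_names: list[str] = field(default_factory=list)


def detect_points(
    spectrum: Spectrum,
    specs: list[CharacteristicPointSpec] | None = None,
) -> CharacteristicPoints:
    """Locate the characteristic points of one (preprocessed) spectrum.

    Minima/maxima are the window argmin/argmax.  Derivative zeros are sign
    changes of the central-difference first derivative inside the window;
    the crossing closest to the nominal wavelength wins and its position is
    linearly interpolated between grid points.  When a window holds no
    crossing the extremum of |derivative| is used and ``found`` is False.

    Because the water-region windows overlap, each derivative-zero landmark
    claims its crossing: later landmarks take the nearest unclaimed one, so
    two landmarks never coincide (which would make the pair slope
    undefined).
    """
    if specs is None:
        specs = default_point_specs()
    grid, y = spectrum.grid, spectrum.intensity
    deriv = np.gradient(y, grid)

    wl = np.empty(len(specs))
    val = np.empty(len(specs))
    found = np.zeros(len(specs), dtype=bool)
    claimed: set[float] = set()

    def window_indices(spec: CharacteristicPointSpec) -> np.ndarray:
        lo, hi = spec.window
        if lo < grid[0] or hi > grid[-1]:
            raise ValueError(
                f"point {spec.index}: window ({lo}, {hi}) nm outside grid "
                f"({grid[0]}, {grid[-1]}) nm"
            )
        return np.nonzero((grid >= lo) & (grid <= hi))[0]

    for k, spec in enumerate(specs):
        if spec.mode == "derivative_zero":
            continue
        sel = window_indices(spec)
        seg = y[sel]
        idx = sel[int(np.argmin(seg) if spec.mode == "minimum" else np.argmax(seg))]
        interior = sel[0] < idx < sel[-1]
        wl[k], val[k], found[k] = grid[idx], y[idx], bool(interior)
        claimed.add(float(grid[idx]))

    for k, spec in enumerate(specs):
        if spec.mode != "derivative_zero":
            continue
        sel = window_indices(spec)
        dseg = deriv[sel]
        signs = np.sign(dseg)
        cross = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
        candidates: list[tuple[float, float]] = []
        for c in cross:
            i0, i1 = sel[c], sel[c + 1]
            frac = deriv[i0] / (deriv[i0] - deriv[i1])
            x = grid[i0] + frac * (grid[i1] - grid[i0])
            v = y[i0] + frac * (y[i1] - y[i0])
            candidates.append((float(x), float(v)))
        # an exact zero flanked by opposite signs is a crossing at that point
        for c in np.nonzero(signs[1:-1] == 0)[0] + 1:
            if signs[c - 1] * signs[c + 1] < 0:
                candidates.append((float(grid[sel[c]]), float(y[sel[c]])))
        candidates = [c for c in candidates if c[0] not in claimed]
        if candidates:
            nominal = spec.nominal if spec.nominal is not None else sum(spec.window) / 2
            x, v = min(candidates, key=lambda c: abs(c[0] - nominal))
            wl[k], val[k], found[k] = x, v, True
        else:
            free = np.array([i for i in sel if float(grid[i]) not in claimed], dtype=int)
            if free.size == 0:  # pathological: every window point claimed
                free = sel
            idx = free[int(np.argmax(np.abs(deriv[free])))]
            wl[k], val[k], found[k] = grid[idx], y[idx], False
        claimed.add(float(wl[k]))
    return CharacteristicPoints(wl, val, found)


def gradient_names(n_points: int = 9) -> list[str]:
    return [f"grad_{i + 1}_{j + 1}" for i in range(n_points) for j in range(n_points)]


def gradients(points: CharacteristicPoints) -> np.ndarray:
    """Slopes between every ordered pair of landmarks, row-major 9x9 -> 81.

    ``g[i][j] = (v_j - v_i) / |wl_j - wl_i|`` for i != j, in (intensity
    units)/nm; the diagonal is zero by definition.  The absolute wavelength
    difference makes the matrix antisymmetric, ``g[i][j] = -g[j][i]``.  Two
    landmarks at the same wavelength would make the slope undefined.
    """
    wl, v = points.wavelength, points.value
    dwl = np.abs(wl[None, :] - wl[:, None])
    off = ~np.eye(len(points), dtype=bool)
    if np.any(dwl[off] == 0):
        raise ValueError("degenerate point pair: two landmarks share a wavelength")
    g = np.zeros((len(points), len(points)))
    np.divide(v[None, :] - v[:, None], dwl, out=g, where=off)
    return g.ravel()


def gradient_feature_matrix(
    spectra: SpectraSet,
    specs: list[CharacteristicPointSpec] | None = None,
) -> FeatureMatrix:
    """Detect points in every spectrum and assemble the 81-gradient matrix."""
    if specs is None:
        specs = default_point_specs()
    n_points = len(specs)
    rows = np.empty((len(spectra), n_points * n_points))
    for i in range(len(spectra)):
        pts = detect_points(spectra.spectrum(i), specs)
        rows[i] = gradients(pts)
    return FeatureMatrix(rows, gradient_names(n_points), spectra.labels.copy())


def anova_f(features: FeatureMatrix) -> FRanking:
    """One-way ANOVA F ratio per feature across the class labels.

    F = [SSB/(K-1)] / [SSW/(N-K)].  Zero within-class variance with a
    nonzero between-class spread yields +inf (which ranks first); zero
    numerator yields 0.
    """
    labels = features.labels
    classes = pd.unique(labels)
    if classes.size < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    counts = np.array([(labels == c).sum() for c in classes])
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 observations")

    X = features.values
    n, k = X.shape[0], classes.size
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c, nc in zip(classes, counts):
        sub = X[labels == c]
        mu = sub.mean(axis=0)
        ssb += nc * (mu - grand) ** 2
        ssw += ((sub - mu) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0),
                     np.where(msb > 0, np.inf, 0.0))
    order = np.lexsort((np.arange(f.size), -f))
    return FRanking(f, order, list(features.feature_names))


def select_top_k(ranking: FRanking, k: int) -> np.ndarray:
    """Indices of the k largest-F features, descending, ties by smaller index."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > ranking.f_values.size:
        raise ValueError("k exceeds the number of features")
    return ranking.order[:k].copy()
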