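"""Seeded synthetic diffuse-reflectance spectra.

The generator emulates the statistical structure of an ex vivo tissue
measurement campaign: five tissue classes (fat, skin, nerve, bone, muscle),
ten specimens per class, two samples per specimen, sixteen measurement
points per sample and four repeated measurements per point, on a
220-1100 nm grid with 0.5 nm resolution (6400 spectra in total under the
default design).

Each noiseless class template follows a multiplicative Beer-Lambert-like
model

    R(lambda) = scatter * B(lambda) * exp(-sum_c w_c A_c(lambda))

where ``B`` is a smooth scattering baseline with a sigmoidal decay starting
near 650 nm and a UV roll-off, and each ``A_c`` is a Gaussian absorption
band of a tissue chromophore (protein ~280 nm, hemoglobin Soret bands near
410/430 nm, hemoglobin beta/alpha bands at 540/575 nm, lipid near 930 nm,
water near 970 nm).  Band centres and the per-tissue weights are placed so
that every noiseless template exhibits the nine spectral landmarks the
feature extractor looks for (minima at 410/540/575 nm, maxima between
them, and three derivative zeros in the 930-970 nm lipid/water region).

Measurement artifacts are layered on top: log-normal multiplicative gains
per specimen, sample and point; one random linear trend and one random
integer grid shift per sample (exercising detrend and alignment); and
additive white noise per wavelength and measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import CLASS_ORDER, META_COLUMNS, Spectrum, SpectraSet, default_grid, validate_grid

__all__ = [
    "ChromophoreBand",
    "TissueProfile",
    "DesignConfig",
    "RandomEffects",
    "default_bands",
    "default_tissue_profiles",
    "template_spectrum",
    "generate_spectrum",
    "generate_dataset",
]


@dataclass(frozen=True)
class ChromophoreBand:
    """Gaussian absorption band: centre and width in nm, unit peak absorbance."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")

    def absorbance(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(-((grid - self.center) ** 2) / (2.0 * self.width**2))


def default_bands() -> dict[str, ChromophoreBand]:
    """Chromophore bands of the synthetic tissue model.

    Centres sit where the corresponding landmark appears in tissue spectra
    (the lipid/water bands are placed at their in-tissue positions, 934 and
    966 nm, so that the lipid minimum, the inter-band maximum and the water
    valley fall inside the standard search windows).
    """
    return {
        "protein_280": ChromophoreBand(280.0, 14.0),
        "hb_410": ChromophoreBand(410.0, 8.0),
        "hb_432": ChromophoreBand(432.0, 9.0),
        "hb_540": ChromophoreBand(540.0, 10.0),
        "hb_575": ChromophoreBand(575.0, 8.0),
        "lipid_930": ChromophoreBand(934.0, 9.0),
        "water_970": ChromophoreBand(968.0, 11.0),
    }


@dataclass
class TissueProfile:
    """Spectral and variance parameters of one tissue class.

    ``band_weights`` are dimensionless absorbances applied to the shared
    chromophore bands.  The ``*_sd`` fields control the hierarchy of random
    effects: multiplicative log-normal gains (specimen/sample/point),
    additive white noise per measurement, a per-sample linear trend
    (intensity per nm) and a per-sample integer grid shift (in 0.5 nm
    steps).
    """

    name: str
    band_weights: dict[str, float]
    scatter_level: float = 1.0
    decay_center: float = 650.0
    decay_width: float = 60.0
    uv_center: float = 260.0
    uv_width: float = 30.0
    specimen_sd: float = 0.08
    sample_sd: float = 0.06
    point_sd: float = 0.04
    noise_sd: float = 0.01
    trend_slope_sd: float = 2.0e-4
    shift_sd: float = 1.2

    def __post_init__(self) -> None:
        for attr in ("specimen_sd", "sample_sd", "point_sd", "noise_sd",
                     "trend_slope_sd", "shift_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be non-negative")

    def noiseless(self) -> "TissueProfile":
        """Copy with every variance parameter set to zero."""
        return replace(
            self,
            band_weights=dict(self.band_weights),
            specimen_sd=0.0,
            sample_sd=0.0,
            point_sd=0.0,
            noise_sd=0.0,
            trend_slope_sd=0.0,
            shift_sd=0.0,
        )


def default_tissue_profiles() -> dict[str, TissueProfile]:
    """The five default tissue classes, in fixed class order.

    Weights are chosen so that classes are separable at the default noise
    level and obey the qualitative contrasts of tissue optics: fat is
    lipid-rich, muscle and bone are hemoglobin-rich, and every tissue
    carries nonzero hemoglobin-575 and water bands.
    """
    rows = {
        # protein hb410 hb432 hb540 hb575 lipid water  scatter  dc    dw
        "fat":    (0.25, 0.55, 0.35, 0.20, 0.16, 0.60, 0.26, 1.15, 670.0, 70.0),
        "skin":   (0.50, 0.85, 0.55, 0.30, 0.27, 0.40, 0.30, 1.00, 640.0, 55.0),
        "nerve":  (0.35, 0.70, 0.45, 0.24, 0.21, 0.46, 0.33, 0.90, 655.0, 60.0),
        "bone":   (0.45, 1.00, 0.62, 0.36, 0.30, 0.40, 0.28, 1.05, 662.0, 65.0),
        "muscle": (0.40, 1.30, 0.78, 0.52, 0.44, 0.34, 0.26, 0.82, 628.0, 50.0),
    }
    band_names = ("protein_280", "hb_410", "hb_432", "hb_540", "hb_575",
                  "lipid_930", "water_970")
    profiles = {}
    for name in CLASS_ORDER:
        *weights, scatter, dc, dw = rows[name]
        profiles[name] = TissueProfile(
            name=name,
            band_weights=dict(zip(band_names, weights)),
            scatter_level=scatter,
            decay_center=dc,
            decay_width=dw,
        )
    return profiles


@dataclass
class DesignConfig:
    """Experimental design: counts per hierarchy level and the master seed."""

    n_tissues: int = 5
    n_specimens: int = 10
    n_samples_per_specimen: int = 2
    n_points: int = 16
    n_measurements: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("n_tissues", "n_specimens", "n_samples_per_specimen",
                     "n_points", "n_measurements"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        if self.n_tissues > len(CLASS_ORDER):
            raise ValueError(f"at most {len(CLASS_ORDER)} tissue classes available")

    @property
    def n_spectra(self) -> int:
        return (self.n_tissues * self.n_specimens * self.n_samples_per_specimen
                * self.n_points * self.n_measurements)


@dataclass
class RandomEffects:
    """Realized random effects entering one spectrum."""

    gain: float = 1.0
    slope: float = 0.0          # intensity units per nm
    shift: int = 0              # grid steps, positive moves features to longer wavelengths
    noise: np.ndarray | None = None


def _baseline(profile: TissueProfile, grid: np.ndarray) -> np.ndarray:
    """Smooth scattering baseline: UV roll-off times post-650 nm decay."""
    uv = expit((grid - profile.uv_center) / profile.uv_width)
    decay = 0.35 + 0.65 * expit((profile.decay_center - grid) / profile.decay_width)
    return uv * decay


def template_spectrum(
    profile: TissueProfile,
    grid: np.ndarray | None = None,
    bands: dict[str, ChromophoreBand] | None = None,
) -> Spectrum:
    """Deterministic noiseless class template (all effects neutral)."""
    if grid is None:
        grid = default_grid()
    grid = validate_grid(grid)
    if bands is None:
        bands = default_bands()
    unknown = set(profile.band_weights) - set(bands)
    if unknown:
        raise ValueError(f"profile {profile.name!r} references unknown bands: {sorted(unknown)}")
    absorbance = np.zeros_like(grid)
    for name, weight in profile.band_weights.items():
        absorbance += weight * bands[name].absorbance(grid)
    intensity = profile.scatter_level * _baseline(profile, grid) * np.exp(-absorbance)
    return Spectrum(grid, intensity, {"tissue": profile.name})


def _apply_shift(values: np.ndarray, shift: int) -> np.ndarray:
    """Shift a vector by an integer number of grid steps, edge-replicated."""
    if shift == 0:
        return values
    out = np.empty_like(values)
    if shift > 0:
        out[shift:] = values[:-shift]
        out[:shift] = values[0]
    else:
        out[:shift] = values[-shift:]
        out[shift:] = values[-1]
    return out


def generate_spectrum(
    profile: TissueProfile,
    grid: np.ndarray,
    effects: RandomEffects,
    bands: dict[str, ChromophoreBand] | None = None,
    template: np.ndarray | None = None,
) -> Spectrum:
    """Realize one spectrum from a profile and its random effects.

    With neutral effects (gain 1, slope 0, shift 0, no noise) the output is
    exactly the noiseless template.  ``template`` may be passed to avoid
    recomputing the class template for every measurement.
    """
    grid = validate_grid(grid)
    if template is None:
        template = template_spectrum(profile, grid, bands).intensity
    if not np.isfinite([effects.gain, effects.slope]).all():
        raise ValueError("random effects must be finite")
    mid = 0.5 * (grid[0] + grid[-1])
    intensity = effects.gain * template + effects.slope * (grid - mid)
    if effects.noise is not None:
        noise = np.asarray(effects.noise, dtype=float)
        if noise.shape != grid.shape:
            raise ValueError("noise vector length must match grid")
        intensity = intensity + noise
    intensity = _apply_shift(intensity, int(effects.shift))
    if not np.all(np.isfinite(intensity)):
        raise ValueError("generated spectrum contains non-finite values")
    return Spectrum(grid, intensity, {"tissue": profile.name})


def generate_dataset(
    design: DesignConfig,
    profiles: dict[str, TissueProfile] | None = None,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    bands: dict[str, ChromophoreBand] | None = None,
) -> SpectraSet:
    """Generate a full seeded dataset with hierarchical random effects.

    Effects are drawn once per hierarchy unit and shared by everything
    nested inside it: a specimen gain is common to both of its samples, a
    sample's gain/trend/shift are common to its 16 points, a point gain is
    common to its 4 measurements, and only the additive noise is redrawn
    per measurement.  A single master seed deterministically spawns one
    substream per hierarchy unit, so datasets are reproducible.
    """
    if profiles is None:
        profiles = default_tissue_profiles()
    if seed is None:
        seed = design.seed
    if grid is None:
        grid = default_grid()
    grid = validate_grid(grid)
    if bands is None:
        bands = default_bands()

    tissues = CLASS_ORDER[: design.n_tissues]
    missing = [t for t in tissues if t not in profiles]
    if missing:
        raise ValueError(f"no tissue profile provided for: {', '.join(missing)}")

    n = design.n_spectra
    matrix = np.empty((n, grid.size))
    labels = np.empty(n, dtype=object)
    meta_rows: list[tuple] = []
    root = np.random.SeedSequence(int(seed))
    tissue_streams = root.spawn(len(tissues))

    row = 0
    for t_idx, tissue in enumerate(tissues):
        profile = profiles[tissue]
        template = template_spectrum(profile, grid, bands).intensity
        specimen_streams = tissue_streams[t_idx].spawn(design.n_specimens)
        for sp in range(design.n_specimens):
            sp_ss = specimen_streams[sp]
            sp_rng = np.random.default_rng(sp_ss)
            sp_gain = float(np.exp(sp_rng.normal(0.0, profile.specimen_sd)))
            sample_streams = sp_ss.spawn(design.n_samples_per_specimen)
            for sa in range(design.n_samples_per_specimen):
                sa_ss = sample_streams[sa]
                sa_rng = np.random.default_rng(sa_ss)
                sa_gain = float(np.exp(sa_rng.normal(0.0, profile.sample_sd)))
                slope = float(sa_rng.normal(0.0, profile.trend_slope_sd))
                shift = int(np.clip(round(sa_rng.normal(0.0, profile.shift_sd)), -8, 8))
                point_streams = sa_ss.spawn(design.n_points)
                for pt in range(design.n_points):
                    pt_ss = point_streams[pt]
                    pt_rng = np.random.default_rng(pt_ss)
                    pt_gain = float(np.exp(pt_rng.normal(0.0, profile.point_sd)))
                    meas_rng = np.random.default_rng(pt_ss.spawn(1)[0])
                    gain = sp_gain * sa_gain * pt_gain
                    for me in range(design.n_measurements):
                        noise = (meas_rng.normal(0.0, profile.noise_sd, grid.size)
                                 if profile.noise_sd > 0 else None)
                        eff = RandomEffects(gain=gain, slope=slope, shift=shift, noise=noise)
                        spec = generate_spectrum(profile, grid, eff, bands, template=template)
                        matrix[row] = spec.intensity
                        labels[row] = tissue
                        meta_rows.append(
                            (f"s{row:06d}", tissue, f"{tissue}_sp{sp:02d}",
                             f"{tissue}_sp{sp:02d}_sa{sa}", pt, me)
                        )
                        row += 1

    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    return SpectraSet(grid, matrix, labels, meta, steps=["simulate"])
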