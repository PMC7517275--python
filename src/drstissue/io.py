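"""File formats and run configuration.

Spectra travel as a wide CSV: first column ``wavelength_nm`` (strictly
increasing), one column per spectrum named by its spectrum id.  A sidecar
``<name>.meta.csv`` carries one row per spectrum with the hierarchical
metadata (tissue, specimen, sample, point, measurement).  The round trip
preserves intensities to 12 significant digits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CLASS_ORDER, META_COLUMNS, SpectraSet
from .preprocess import PreprocessConfig
from .synthetic import DesignConfig

__all__ = [
    "RunConfig",
    "read_spectra",
    "write_spectra",
    "meta_path_for",
]


def meta_path_for(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.csv")


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ids = spectra.meta["spectrum_id"].astype(str).to_numpy()
    if pd.Index(ids).has_duplicates:
        raise ValueError("duplicated spectrum_id in metadata")
    frame = pd.DataFrame(spectra.matrix.T, columns=ids)
    frame.insert(0, "wavelength_nm", spectra.grid)
    frame.to_csv(path, index=False, float_format="%.12g")
    spectra.meta.loc[:, list(META_COLUMNS)].to_csv(meta_path_for(path), index=False)


def read_spectra(path: str | Path) -> SpectraSet:
    path = Path(path)
    meta_path = meta_path_for(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    frame = pd.read_csv(path)
    if frame.columns[0] != "wavelength_nm":
        raise ValueError("first column must be wavelength_nm")
    grid = frame["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength_nm must be strictly increasing")
    ids = list(frame.columns[1:])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated spectrum_id column in spectra file")
    meta = pd.read_csv(meta_path, dtype={"spectrum_id": str})
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata sidecar missing columns: {sorted(missing)}")
    if meta["spectrum_id"].duplicated().any():
        raise ValueError("duplicated spectrum_id in metadata")
    meta = meta.set_index("spectrum_id", drop=False).loc[ids].reset_index(drop=True)
    bad = set(meta["tissue"].unique()) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    matrix = frame[ids].to_numpy(dtype=float).T
    return SpectraSet(grid, matrix, meta["tissue"].to_numpy(), meta)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, serializable to YAML."""

    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_top_gradients: int = 14
    n_pca_components: int = 40
    train_fraction: float = 0.2
    split_unit: str = "spectrum"
    n_repeats: int = 20
    aggregate_measurements: bool = False
    classifiers: dict = field(default_factory=lambda: {
        "lda": {},
        "qda": {},
        "knn": {"k": 5},
        "cart": {"max_depth": 20, "min_leaf": 5},
        "nb": {},
    })
    profile_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["design"] = asdict(self.design)
        out["preprocess"] = asdict(self.preprocess)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "design" in data:
            data["design"] = DesignConfig(**data["design"])
        if "preprocess" in data:
            data["preprocess"] = PreprocessConfig(**data["preprocess"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
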