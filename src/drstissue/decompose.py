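"""Principal component analysis for spectral dimensionality reduction.

Spectra live on a ~1761-point grid; most of their variance is captured by
a few dozen principal directions of the sample covariance matrix.  The
model keeps the data mean, the leading orthonormal eigenvectors and their
eigenvalues, supports projection and reconstruction, and reports the
cumulative explained-variance ratio.  Components are computed by SVD of
the centered data (equivalent to the covariance eigendecomposition) with a
deterministic sign convention: the largest-magnitude entry of each
component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import SpectraSet
from .features import FeatureMatrix

__all__ = [
    "PCAModel",
    "pca_fit",
    "pca_transform",
    "pca_reconstruct",
    "explained_similarity",
    "save_pca_model",
    "load_pca_model",
]


@dataclass
class PCAModel:
    mean: np.ndarray            # length D
    components: np.ndarray      # (M, D), orthonormal rows
    eigenvalues: np.ndarray     # length M, non-increasing
    total_variance: float       # trace of the sample covariance

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.components.shape[1]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraSet):
        return X.matrix
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def pca_fit(X, n_components: int) -> PCAModel:
    """Fit PCA with the top ``n_components`` eigenpairs of the sample covariance.

    Uses the 1/(N-1) covariance convention; requires
    ``n_components <= min(N - 1, D)`` since at most N-1 directions carry
    sample variance.
    """
    data = _as_matrix(X)
    n, d = data.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    if not (1 <= n_components <= min(n - 1, d)):
        raise ValueError(
            f"n_components must be in [1, min(N-1, D)] = [1, {min(n - 1, d)}]"
        )
    mean = data.mean(axis=0)
    centered = data - mean
    if d <= n:
        # symmetric eigendecomposition of the sample covariance
        cov = centered.T @ centered / (n - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        eigenvalues = np.maximum(w[order], 0.0)
        vt = v[:, order].T
    else:
        # tall data: SVD of the centered matrix is cheaper and equivalent
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
    components = vt[:n_components]
    # deterministic sign: largest-|entry| positive
    flip = np.sign(components[np.arange(n_components),
                              np.argmax(np.abs(components), axis=1)])
    components = components * flip[:, None]
    return PCAModel(
        mean=mean,
        components=components,
        eigenvalues=eigenvalues[:n_components].copy(),
        total_variance=float(eigenvalues.sum()),
    )


def pca_transform(model: PCAModel, X) -> np.ndarray:
    """Scores of the centered data: (X - mean) @ components.T."""
    data = _as_matrix(X)
    if data.shape[1] != model.n_dimensions:
        raise ValueError(
            f"data has {data.shape[1]} columns, model expects {model.n_dimensions}"
        )
    return (data - model.mean) @ model.components.T


def pca_reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Back-projection: mean + scores @ components."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != model.n_components:
        raise ValueError(f"scores must be (N, {model.n_components})")
    return model.mean + scores @ model.components


def explained_similarity(model: PCAModel, n_components: int) -> float:
    """Cumulative explained-variance ratio of the first ``n_components``."""
    if not (1 <= n_components <= model.n_components):
        raise ValueError("n_components out of range")
    if model.total_variance == 0:
        return 1.0
    return float(model.eigenvalues[:n_components].sum() / model.total_variance)


def save_pca_model(model: PCAModel, path: str | Path) -> None:
    """Self-describing text serialization: header, mean, eigenvalues, components."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# drstissue PCA model: M={model.n_components} D={model.n_dimensions}\n")
        fh.write(f"total_variance,{model.total_variance!r}\n")
        fh.write("mean," + ",".join(repr(float(v)) for v in model.mean) + "\n")
        fh.write("eigenvalues," + ",".join(repr(float(v)) for v in model.eigenvalues) + "\n")
        for m in range(model.n_components):
            fh.write(f"component_{m}," + ",".join(repr(float(v)) for v in model.components[m]) + "\n")


def load_pca_model(path: str | Path) -> PCAModel:
    path = Path(path)
    rows: dict[str, np.ndarray] = {}
    components = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split(",")
            vec = np.array([float(v) for v in vals])
            if key.startswith("component_"):
                components.append(vec)
            else:
                rows[key] = vec
    return PCAModel(
        mean=rows["mean"],
        components=np.vstack(components),
        eigenvalues=rows["eigenvalues"],
        total_variance=float(rows["total_variance"][0]),
    )
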