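"""Confusion matrices and the tissue-classification metric conventions.

The reporting conventions follow the DRS tissue-discrimination literature:

* sensitivity of class c = per-class recall, ``M[c][c] / rowsum_c``;
* "specificity" of class c = per-class precision (positive predictive
  value), ``M[c][c] / colsum_c`` — note this is NOT the true-negative
  rate; the TNR is available separately under its correct name;
* averages are support-weighted (weights = true-class counts), which makes
  the average sensitivity identical to the overall accuracy;
* accuracy = trace / total.

Two published LDA confusion matrices (one per feature path) ship as CSV
fixtures; :func:`reproduce_reference_tables` recomputes every tabulated
metric from them and compares against the published, rounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "sensitivity",
    "specificity",
    "true_negative_rate",
    "accuracy",
    "averages",
    "metrics_report",
    "round_half_up",
    "load_fixture_matrix",
    "reproduce_reference_tables",
]


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion(y_true, y_pred, classes: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def sensitivity(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall; NaN where a class has no true instances."""
    rows = cm.row_totals().astype(float)
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)


def specificity(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class precision (the quantity tabulated as "specificity")."""
    cols = cm.col_totals().astype(float)
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)


def true_negative_rate(cm: ConfusionMatrix) -> np.ndarray:
    """Textbook specificity TN / (TN + FP), for reference."""
    total = cm.total
    diag = np.diag(cm.counts).astype(float)
    rows = cm.row_totals().astype(float)
    cols = cm.col_totals().astype(float)
    tn = total - rows - cols + diag
    fp = cols - diag
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tn + fp > 0, tn / np.where(tn + fp > 0, tn + fp, 1), np.nan)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def averages(cm: ConfusionMatrix) -> tuple[float, float]:
    """Support-weighted (average sensitivity, average specificity).

    Weights are the true-class supports (row totals); with this convention
    the average sensitivity equals the overall accuracy.
    """
    rows = cm.row_totals().astype(float)
    w = rows / rows.sum()
    sens = sensitivity(cm)
    spec = specificity(cm)
    return float(np.nansum(w * sens)), float(np.nansum(w * spec))


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (0.875 -> 0.88)."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


@dataclass
class MetricsReport:
    classes: tuple[str, ...]
    sensitivity: np.ndarray
    specificity: np.ndarray
    avg_sensitivity: float
    avg_specificity: float
    accuracy: float

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rnd = (lambda v: round_half_up(v, decimals)) if decimals is not None else (lambda v: v)
        rows = [
            {"tissue": c, "specificity": rnd(p), "sensitivity": rnd(s)}
            for c, p, s in zip(self.classes, self.specificity, self.sensitivity)
        ]
        rows.append({
            "tissue": "average",
            "specificity": rnd(self.avg_specificity),
            "sensitivity": rnd(self.avg_sensitivity),
        })
        return pd.DataFrame(rows)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    avg_sens, avg_spec = averages(cm)
    return MetricsReport(
        cm.classes, sensitivity(cm), specificity(cm), avg_sens, avg_spec, accuracy(cm)
    )


# ---------------------------------------------------------------------------
# reference-table reproduction

#: Published rounded values recomputed by :func:`reproduce_reference_tables`.
_REFERENCE = {
    "gradients": {
        "sensitivity": (0.89, 0.84, 0.88, 0.74, 0.75),
        "specificity": (0.69, 0.94, 0.94, 0.77, 0.85),
        "avg_sensitivity": 0.82,
        "avg_specificity": 0.83,
        "accuracy": 0.818,
    },
    "pca": {
        "sensitivity": (1.00, 1.00, 1.00, 0.99, 0.99),
        "specificity": (0.98, 1.00, 1.00, 0.99, 1.00),
        "avg_sensitivity": 0.99,
        "avg_specificity": 0.99,
        "accuracy": 0.993,
    },
}

_FIXTURES = {"gradients": "eq4_confusion.csv", "pca": "eq6_confusion.csv"}


def load_fixture_matrix(path_name: str) -> ConfusionMatrix:
    """Load one of the shipped reference confusion matrices (or a CSV path)."""
    candidate = Path(path_name)
    if candidate.suffix == ".csv" and candidate.exists():
        source = candidate
    else:
        if path_name not in _FIXTURES:
            raise FileNotFoundError(
                f"unknown fixture {path_name!r}; expected one of {sorted(_FIXTURES)} "
                "or a CSV path"
            )
        source = resources.files("drstissue.fixtures") / _FIXTURES[path_name]
        if not source.is_file():
            raise FileNotFoundError(f"fixture file missing: {source}")
    frame = pd.read_csv(str(source), comment="#", index_col=0)
    counts = frame.loc[list(CLASS_ORDER), list(CLASS_ORDER)].to_numpy()
    return ConfusionMatrix(counts.astype(int))


def reproduce_reference_tables(decimals_class: int = 2, decimals_acc: int = 3) -> pd.DataFrame:
    """Recompute every published LDA table cell from the fixture matrices.

    Per-class cells and the averages are compared at 2 decimals; the
    accuracies at 3 decimals.  A cell passes when the recomputed value
    rounds (half-up) to the published one or differs from it by less than
    one unit in the last published digit — the published accuracies are
    means over repeated splits, so the single-matrix accuracy may sit one
    rounding unit away.
    """
    records = []
    for path, fixture in _FIXTURES.items():
        cm = load_fixture_matrix(path)
        report = metrics_report(cm)
        ref = _REFERENCE[path]
        cells: list[tuple[str, float, float, int]] = []
        for i, c in enumerate(cm.classes):
            cells.append((f"sensitivity_{c}", report.sensitivity[i],
                          ref["sensitivity"][i], decimals_class))
            cells.append((f"specificity_{c}", report.specificity[i],
                          ref["specificity"][i], decimals_class))
        cells.append(("avg_sensitivity", report.avg_sensitivity,
                      ref["avg_sensitivity"], decimals_class))
        cells.append(("avg_specificity", report.avg_specificity,
                      ref["avg_specificity"], decimals_class))
        cells.append(("accuracy", report.accuracy, ref["accuracy"], decimals_acc))
        for name, computed, published, dec in cells:
            ok = (round_half_up(computed, dec) == published
                  or abs(computed - published) < 10.0 ** (-dec))
            records.append({
                "path": path,
                "cell": name,
                "computed": computed,
                "published": published,
                "decimals": dec,
                "match": bool(ok),
                "row_totals": tuple(int(v) for v in cm.row_totals()),
            })
    return pd.DataFrame(records)
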