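"""End-to-end pipelines tying the stages together.

Two feature paths feed the same classifier battery:

* the *characteristics* path: preprocess -> detect the nine landmarks ->
  81 gradient features -> ANOVA-F ranking -> keep the top 14;
* the *PCA* path: preprocess -> PCA on the full spectra -> 40 scores.

Each path is evaluated with every classifier under repeated stratified
one-fifth-training splits, and the artifacts (feature tables, metrics,
confusion matrices, lag tables, run log) are written to disk.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import Classifier, make_classifier, make_split, repeated_evaluation
from .core import SpectraSet
from .decompose import pca_fit, pca_transform, save_pca_model
from .evaluate import confusion, metrics_report
from .features import FeatureMatrix, anova_f, gradient_feature_matrix, select_top_k
from .io import RunConfig, write_spectra
from .preprocess import preprocess_pipeline
from .synthetic import default_tissue_profiles, generate_dataset

__all__ = ["build_feature_paths", "run_pipeline", "apply_profile_overrides",
           "aggregate_measurements"]


def apply_profile_overrides(profiles: dict, overrides: dict) -> dict:
    """Apply per-tissue field overrides, e.g. {'fat': {'noise_sd': 0.0}}."""
    out = {name: prof for name, prof in profiles.items()}
    for tissue, fields in overrides.items():
        if tissue == "all":
            continue
        if tissue not in out:
            raise ValueError(f"override for unknown tissue {tissue!r}")
    if "all" in overrides:
        overrides = {
            **{name: dict(overrides["all"]) for name in out},
            **{k: v for k, v in overrides.items() if k != "all"},
        }
    from dataclasses import replace

    for tissue, fields in overrides.items():
        out[tissue] = replace(out[tissue], **fields)
    return out


def aggregate_measurements(spectra: SpectraSet) -> SpectraSet:
    """Average the repeated measurements of each point into one spectrum."""
    keys = spectra.meta.groupby(
        ["tissue", "specimen_id", "sample_id", "point_idx"], sort=False
    ).indices
    rows, labels, meta_rows = [], [], []
    for (tissue, specimen, sample, point), idx in keys.items():
        rows.append(spectra.matrix[idx].mean(axis=0))
        labels.append(tissue)
        meta_rows.append((f"s{len(meta_rows):06d}", tissue, specimen, sample, point, 0))
    meta = pd.DataFrame(meta_rows, columns=list(spectra.meta.columns[:6]))
    return SpectraSet(spectra.grid, np.vstack(rows), np.array(labels, dtype=object),
                      meta, steps=spectra.steps + ["aggregate_measurements"])


def build_feature_paths(spectra: SpectraSet, config: RunConfig) -> dict:
    """Preprocess and compute both feature representations.

    Returns a dict with the preprocessed set, the full and top-k gradient
    feature matrices with their F ranking, and the PCA model and scores.
    """
    processed = preprocess_pipeline(spectra, config.preprocess)

    grads = gradient_feature_matrix(processed)
    ranking = anova_f(grads)
    top = select_top_k(ranking, config.n_top_gradients)
    grads_top = grads.select(top)

    pca = pca_fit(processed, config.n_pca_components)
    scores = pca_transform(pca, processed)
    score_features = FeatureMatrix(
        scores, [f"pc_{m + 1}" for m in range(scores.shape[1])], processed.labels.copy()
    )
    return {
        "processed": processed,
        "gradients": grads,
        "ranking": ranking,
        "top_indices": top,
        "gradients_top": grads_top,
        "pca_model": pca,
        "pca_scores": score_features,
    }


def _evaluate_path(features: FeatureMatrix, config: RunConfig, seed: int) -> dict:
    results = {}
    for name, params in config.classifiers.items():
        results[name] = repeated_evaluation(
            features, features.labels, make_classifier(name, params),
            n_repeats=config.n_repeats, train_fraction=config.train_fraction,
            unit=config.split_unit, seed=seed,
        )
    return results


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 spectra: SpectraSet | None = None) -> dict:
    """Run simulate (or use the given set) -> preprocess -> both paths ->
    split/train/evaluate all classifiers, writing artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    if spectra is None:
        profiles = apply_profile_overrides(
            default_tissue_profiles(), config.profile_overrides
        )
        spectra = generate_dataset(config.design, profiles, seed=config.seed)
        timings["simulate"] = time.time() - t0
    if config.aggregate_measurements:
        spectra = aggregate_measurements(spectra)

    t1 = time.time()
    paths = build_feature_paths(spectra, config)
    timings["features"] = time.time() - t1

    paths["gradients_top"].to_frame().to_csv(out / "gradient_features_top.csv", index=False)
    ranking_frame = pd.DataFrame({
        "feature": paths["ranking"].feature_names,
        "f_value": paths["ranking"].f_values,
    }).sort_values("f_value", ascending=False, kind="stable")
    ranking_frame.to_csv(out / "anova_f_ranking.csv", index=False)
    save_pca_model(paths["pca_model"], out / "pca_model.csv")

    t2 = time.time()
    results = {}
    for path_name, feats in (("gradients", paths["gradients_top"]),
                             ("pca", paths["pca_scores"])):
        results[path_name] = _evaluate_path(feats, config, config.seed)
    timings["train_eval"] = time.time() - t2

    accuracy_rows = []
    for path_name, by_clf in results.items():
        for clf, res in by_clf.items():
            accuracy_rows.append({
                "path": path_name, "classifier": clf,
                "mean_accuracy": res["mean_accuracy"],
                "sd_accuracy": res["sd_accuracy"],
            })
    pd.DataFrame(accuracy_rows).to_csv(out / "accuracy_table.csv", index=False)

    # one representative confusion matrix per path (LDA on the first split)
    for path_name, feats in (("gradients", paths["gradients_top"]),
                             ("pca", paths["pca_scores"])):
        plan = make_split(feats.labels, spectra.meta, config.train_fraction,
                          config.split_unit, config.seed)
        clf = make_classifier("lda", config.classifiers.get("lda", {}))
        clf.fit(feats.values[plan.train_indices], feats.labels[plan.train_indices])
        pred = clf.predict(feats.values[plan.test_indices])
        cm = confusion(feats.labels[plan.test_indices], pred)
        frame = pd.DataFrame(cm.counts, index=cm.classes, columns=cm.classes)
        frame.to_csv(out / f"confusion_lda_{path_name}.csv")
        metrics_report(cm).to_frame(decimals=2).to_csv(
            out / f"metrics_lda_{path_name}.csv", index=False
        )

    cfg_text = json.dumps(config.to_dict(), sort_keys=True)
    log = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_spectra": len(spectra),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "numpy": np.__version__,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"results": results, "paths": paths, "log": log, "spectra": spectra}
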