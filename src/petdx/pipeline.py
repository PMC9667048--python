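"""End-to-end experiment driver: simulate -> preprocess -> features ->
ensembles -> metrics -> explanation, from one validated, fully seeded config.

The driver mirrors the study workflow: four metabolic patterns (three
disease-related and one normal/default-mode stand-in) are derived from
designated identification subjects, who are flagged as leakage; both the
pattern-based and the ROI-based classifiers are then run with the *same*
split scheme so their comparison is like-for-like, the ROI classifier both
on the entire cohort and on the reduced evaluation that applies the same
leakage exclusions.  All stage outputs are pure functions of the config, and
a manifest with seeds and content checksums makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

import petdx
from petdx.ensemble import EnsembleResult, SplitScheme, SVMConfig, run_ensemble
from petdx.explain import (
    class_importance_map,
    fit_nca,
    shapley_table_linear,
)
from petdx.metrics import MetricsReport, as_percent, confusion, per_class_metrics, roc_auc_one_vs_all
from petdx.preprocess import global_scale, smooth
from petdx.roifeat import FeatureMatrix, roi_feature_matrix
from petdx.ssmpca import PatternConfig, derive_pattern, pattern_feature_matrix
from petdx.synth import (
    ClassTopography,
    SyntheticCohortSpec,
    default_topographies,
    make_toy_atlas,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_experiment", "evaluate_ensemble"]

#: Pattern-identification subjects per class (also the leakage counts).
DEFAULT_DERIVATION_COUNTS = {"AD": 20, "DLB": 20, "FTD": 10, "NC": 29}


class CohortSection(BaseModel):
    n_per_class: dict[str, int] = {"AD": 63, "DLB": 79, "FTD": 23, "NC": 41}
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_rois: int = 8
    global_scale_sd: float = 0.15
    noise_sd: float = 0.05
    seed: int  # required: every random stage must be explicitly seeded


class TopographySection(BaseModel):
    class_label: str
    affected_rois: tuple[int, ...] = ()
    hypometabolism_fraction: float = 0.0
    variability: float = 0.0


class PatternSection(BaseModel):
    var_threshold: float = 0.5
    mode: str = "best_t"


class SchemeSection(BaseModel):
    n_iterations: int = 100
    train_fraction: float = 0.7
    seed: int


class ClassifierSection(BaseModel):
    C: float = 1.0
    coding: str = "ovo"
    standardize: bool = True


class ExplainSection(BaseModel):
    n_runs: int = 50
    nca_lambda: float = 0.01
    threshold_fraction: float = 0.3
    seed: int


class RunConfig(BaseModel):
    """Schema-validated experiment configuration."""

    fwhm_mm: float = 10.0
    cohort: CohortSection
    topographies: list[TopographySection] | None = None
    derivation_counts: dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_DERIVATION_COUNTS)
    )
    pattern: PatternSection = Field(default_factory=PatternSection)
    scheme: SchemeSection
    classifier: ClassifierSection = Field(default_factory=ClassifierSection)
    explain: ExplainSection


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))


def _checksum(obj) -> str:
    if isinstance(obj, np.ndarray):
        payload = np.ascontiguousarray(obj).tobytes()
    elif isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(index=False).encode()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def evaluate_ensemble(
    result: EnsembleResult, feature_matrix: FeatureMatrix
) -> MetricsReport:
    """Confusion-matrix metrics plus one-vs-all AUC for an ensemble run.

    Only subjects with a final label (tested at least once) enter the
    confusion matrix; the ROC score for each class is the subject's vote
    fraction for that class.
    """
    truth = dict(zip(feature_matrix.subject_ids, feature_matrix.class_labels))
    tested = result.tested_ids()
    cm = confusion(
        [truth[s] for s in tested],
        [result.final_labels[s] for s in tested],
        result.class_order,
    )
    report = per_class_metrics(cm)
    scores = result.class_scores.loc[tested]
    labels = [truth[s] for s in tested]
    report.auc = {
        cls: roc_auc_one_vs_all(scores[cls].to_numpy(), labels, cls)
        for cls in result.class_order
        if cls in set(labels)
    }
    return report


def _derive_all_patterns(volumes, table, config: RunConfig):
    """Derive ADRP/DLBRP/FTDRP stand-ins plus a DMN-like normal pattern.

    Disease patterns come from each class's identification subjects versus
    the NC identification subjects; the normal-pattern stand-in is derived
    from the pooled dementia identification subjects versus NC with the
    sign fixed so controls express it more.
    """
    pc = PatternConfig(var_threshold=config.pattern.var_threshold, mode=config.pattern.mode)
    idx_by_class: dict[str, list[int]] = {}
    for i, (cls, leak) in enumerate(zip(table["class"], table["leakage"])):
        if leak:
            idx_by_class.setdefault(cls, []).append(i)
    nc_vols = [volumes[i] for i in idx_by_class.get("NC", [])]
    if len(nc_vols) < 3:
        raise ValueError("need >= 3 NC identification subjects to derive patterns")
    patterns = []
    pooled = []
    for cls, pat_name in (("AD", "ADRP"), ("DLB", "DLBRP"), ("FTD", "FTDRP")):
        dis = [volumes[i] for i in idx_by_class.get(cls, [])]
        pooled.extend(dis)
        patterns.append(derive_pattern(dis, nc_vols, pc, name=pat_name))
    patterns.append(
        derive_pattern(pooled, nc_vols, pc, name="DMN", positive_group="nc")
    )
    return patterns


def run_experiment(config: RunConfig, out_dir) -> dict:
    """Run every stage in order and return the manifest.

    Writes per-stage outputs (feature CSVs, metrics JSON, importance CSV,
    manifest) under ``out_dir`` and returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": petdx.__version__,
        "config": config.model_dump(),
        "stages": {},
        "checksums": {},
    }

    def _fail(stage: str, exc: Exception):
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- simulate ----------------------------------------------------------
    try:
        spec = SyntheticCohortSpec(**config.cohort.model_dump())
        atlas = make_toy_atlas(
            spec.grid_shape, spec.n_rois, spec.seed, spec.voxel_size_mm
        )
        topos = (
            [ClassTopography(**t.model_dump()) for t in config.topographies]
            if config.topographies
            else default_topographies()
        )
        volumes, table = simulate_cohort(
            spec, topos, atlas, leakage_per_class=config.derivation_counts
        )
        table.to_csv(out / "subjects.csv", index=False)
        manifest["stages"]["simulate"] = {"n_subjects": len(table), "seed": spec.seed}
        manifest["checksums"]["subjects"] = _checksum(table)
        manifest["checksums"]["atlas"] = _checksum(atlas.labels)
    except Exception as exc:  # noqa: BLE001
        _fail("simulate", exc)

    # -- preprocess --------------------------------------------------------
    try:
        processed = []
        for v in volumes:
            scaled, _ = global_scale(smooth(v, config.fwhm_mm))
            processed.append(scaled)
        manifest["stages"]["preprocess"] = {"fwhm_mm": config.fwhm_mm, "order": "smooth->scale"}
        manifest["checksums"]["volumes"] = _checksum(
            np.stack([v.masked_values() for v in processed])
        )
    except Exception as exc:  # noqa: BLE001
        _fail("preprocess", exc)

    # -- patterns + pattern features --------------------------------------
    try:
        patterns = _derive_all_patterns(processed, table, config)
        pattern_fm = pattern_feature_matrix(processed, patterns, table)
        pattern_fm.to_csv(out / "features_pattern.csv")
        manifest["stages"]["patterns"] = {p.name: p.meta for p in patterns}
        manifest["checksums"]["features_pattern"] = _checksum(pattern_fm.values)
    except Exception as exc:  # noqa: BLE001
        _fail("patterns", exc)

    # -- ROI features ------------------------------------------------------
    try:
        roi_fm = roi_feature_matrix(processed, atlas, table)
        roi_fm.to_csv(out / "features_roi.csv")
        manifest["checksums"]["features_roi"] = _checksum(roi_fm.values)
    except Exception as exc:  # noqa: BLE001
        _fail("roi_features", exc)

    # -- ensembles + metrics ----------------------------------------------
    try:
        svm = SVMConfig(**config.classifier.model_dump())
        leak_ids = frozenset(table.loc[table["leakage"], "id"])
        scheme_leak = SplitScheme(
            n_iterations=config.scheme.n_iterations,
            train_fraction=config.scheme.train_fraction,
            leakage_ids=leak_ids,
            master_seed=config.scheme.seed,
        )
        scheme_full = SplitScheme(
            n_iterations=config.scheme.n_iterations,
            train_fraction=config.scheme.train_fraction,
            leakage_ids=frozenset(),
            master_seed=config.scheme.seed,
        )
        evaluations = {}
        results: dict[str, EnsembleResult] = {}
        for name, fm, scheme in (
            ("pattern_reduced", pattern_fm, scheme_leak),
            ("roi_full", roi_fm, scheme_full),
            ("roi_reduced", roi_fm, scheme_leak),
        ):
            res = run_ensemble(fm, scheme, svm)
            report = evaluate_ensemble(res, fm)
            results[name] = res
            evaluations[name] = report.to_dict() | {
                "n_labeled": len(res.final_labels),
                "overall_accuracy_pct": as_percent(report.overall_accuracy),
            }
            res.iteration_records.to_csv(out / f"iterations_{name}.csv", index=False)
            manifest["checksums"][f"final_labels_{name}"] = _checksum(
                pd.DataFrame(
                    sorted(res.final_labels.items()), columns=["id", "label"]
                )
            )
        (out / "metrics.json").write_text(json.dumps(evaluations, indent=2))
        manifest["stages"]["ensemble"] = {
            "n_iterations": config.scheme.n_iterations,
            "seed": config.scheme.seed,
            "evaluations": {k: v["overall_accuracy"] for k, v in evaluations.items()},
        }
    except Exception as exc:  # noqa: BLE001
        _fail("ensemble", exc)

    # -- explanation -------------------------------------------------------
    try:
        X = roi_fm.values
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        nca = fit_nca((X - mu) / sd, roi_fm.labels_array(), config.explain.nca_lambda)
        ranking = [
            roi_fm.feature_names[i] for i in np.argsort(nca.w)[::-1]
        ]
        shap_table = shapley_table_linear(
            roi_fm, scheme_full, svm, n_runs=config.explain.n_runs
        )
        imp = class_importance_map(shap_table, table, atlas)
        rows = [
            {"class": cls, "roi": fname, "importance": float(val)}
            for cls, vals in imp.values.items()
            for fname, val in zip(imp.feature_names, vals)
        ]
        pd.DataFrame(rows).to_csv(out / "importance.csv", index=False)
        manifest["stages"]["explain"] = {
            "nca_lambda": config.explain.nca_lambda,
            "nca_ranking": ranking,
            "shap_runs": config.explain.n_runs,
        }
        manifest["checksums"]["importance"] = _checksum(
            np.stack([imp.values[c] for c in sorted(imp.values)])
        )
    except Exception as exc:  # noqa: BLE001
        _fail("explain", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
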