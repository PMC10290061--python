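"""End-to-end pipeline driver.

Orchestrates synthetic cohort generation (or file input), preprocessing,
CAP extraction with model selection, temporal/spatial metrics, group
statistics and the classification experiment, writing every output plus a
manifest (paths, SHA-256 hashes, seeds) so a run is fully auditable and
rerunning an identical config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as capio
from .classification import compare_to_chance, run_experiment
from .extraction import build_caps, build_variance_curve, concatenate_subjects
from .group_stats import compare_all_caps
from .metrics import roi_seven_categories, significance_for_caps, subject_cap_metrics
from .preprocessing import PreprocessingConfig, preprocess_pipeline
from .synthetic import generate_atlas, generate_cohort, make_model

logger = logging.getLogger("capdyn")


def default_config(seed: int = 0) -> dict:
    """The study-condition configuration on the desk-scale voxel grid."""
    return {
        "seed": seed,
        "synthetic": {
            "grid_dims": [20, 20, 6],
            "k_true": 4,
            "n_frames": 1200,
            "tr": 0.5,
            "group_sizes": [18, 19],
            "mean_dwell": 5.0,
            "dwell_effect": 0.3,
            "amplitude_effect": 0.3,
            "noise_sd": 1.0,
        },
        "preprocessing": {
            "smooth_fwhm": 2.0,
            "trim_pre": [5, 5],
            "trim_post": [5, 5],
            "band": [0.01, 0.2],
            "butter_order": 5,
            "detrend": True,
            "global_signal_regression": True,
            "zscore": True,
        },
        "extraction": {
            "k_min": 2, "k_max": 20, "gain_threshold": 0.005,
            "n_replicates": 5, "max_iter": 100,
        },
        "statistics": {
            "one_sample_alpha": 0.01, "fdr_q": 0.05,
            "temporal_test": "two_sample_t",
        },
        "classification": {
            "feature_kind": "spatial", "n_trials": 50,
            "regularization": 10.0, "train_fraction": 0.8,
            "n_replicates": 2,
        },
    }


def validate_config(config: dict) -> None:
    for key in ("seed", "preprocessing", "extraction", "statistics",
                "classification"):
        if key not in config:
            raise ValueError(f"config is missing section {key!r}")
    if "synthetic" not in config and "paths" not in config:
        raise ValueError("config needs either a 'synthetic' or 'paths' section")
    if "paths" in config:
        for key in ("atlas", "roi_names", "subject_table"):
            if key not in config["paths"]:
                raise ValueError(f"paths section is missing {key!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s: start", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage and return the results bundle.

    The bundle holds the in-memory objects (cohort, pool, curve, caps,
    metric tables, classification run) plus the output manifest.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    results: dict = {"config": config}

    if "synthetic" in config:
        syn = config["synthetic"]
        atlas = _stage("atlas")(generate_atlas,
                                grid_dims=tuple(syn["grid_dims"]), seed=seed)
        model = make_model(
            atlas, k_true=syn["k_true"], n_frames=syn["n_frames"],
            tr=syn["tr"], group_sizes=tuple(syn["group_sizes"]),
            mean_dwell=syn["mean_dwell"], dwell_effect=syn["dwell_effect"],
            amplitude_effect=syn["amplitude_effect"],
            noise_sd=syn["noise_sd"], seed=seed)
        cohort = _stage("simulate")(generate_cohort, model, atlas, seed=seed)
        raw_series = cohort.subjects
        results["cohort"] = cohort
    else:
        paths = config["paths"]
        atlas = _stage("read_atlas")(capio.read_atlas, paths["atlas"],
                                     paths["roi_names"])
        table = capio.read_subject_table(paths["subject_table"])
        raw_series = [capio.read_series(paths["series"][row.subject_id],
                                        atlas.brain_mask,
                                        subject_id=row.subject_id,
                                        group=row.group)
                      for row in table.itertuples()]
    results["atlas"] = atlas

    pp = config["preprocessing"]
    pcfg = PreprocessingConfig(
        smooth_fwhm=pp.get("smooth_fwhm"),
        trim_pre=tuple(pp.get("trim_pre", (5, 5))),
        trim_post=tuple(pp.get("trim_post", (5, 5))),
        single_trim=pp.get("single_trim", False),
        band=tuple(pp["band"]) if pp.get("band") else None,
        butter_order=pp.get("butter_order", 5),
        detrend=pp.get("detrend", True),
        global_signal_regression=pp.get("global_signal_regression", True),
        zscore=pp.get("zscore", True))
    processed = _stage("preprocess")(
        lambda: [preprocess_pipeline(s, pcfg) for s in raw_series])
    results["processed"] = processed

    ext = config["extraction"]
    pool = _stage("concatenate")(concatenate_subjects, processed,
                                 atlas.analysis_mask)
    curve = _stage("variance_curve")(
        build_variance_curve, pool, k_min=ext["k_min"], k_max=ext["k_max"],
        seed=seed, n_replicates=ext["n_replicates"],
        max_iter=ext["max_iter"], gain_threshold=ext["gain_threshold"])
    k_opt = curve.selected_k
    from .extraction import kmeans_corr
    solution = _stage("cluster")(kmeans_corr, pool, k_opt, seed=seed,
                                 n_replicates=ext["n_replicates"],
                                 max_iter=ext["max_iter"])
    capset = _stage("caps")(build_caps, pool, solution)
    st = config["statistics"]
    capset = _stage("significance")(significance_for_caps, pool, capset,
                                    alpha=st["one_sample_alpha"],
                                    q=st["fdr_q"])
    results.update(pool=pool, curve=curve, solution=solution, capset=capset)

    tr = processed[0].tr
    metrics_df = _stage("metrics")(subject_cap_metrics, pool,
                                   solution.labels, k_opt, tr)
    roi_tables = pd.concat(
        [roi_seven_categories(capset, atlas, cap.cap_id) for cap in capset],
        ignore_index=True)
    comparisons = pd.concat([
        compare_all_caps(metrics_df, "mean_duration_frames",
                         test=st["temporal_test"], q=st["fdr_q"]),
        compare_all_caps(metrics_df, "occurrence_pct",
                         test=st["temporal_test"], q=st["fdr_q"]),
    ], ignore_index=True)
    results.update(metrics=metrics_df, roi_categories=roi_tables,
                   comparisons=comparisons)

    cl = config["classification"]
    run = _stage("classification")(
        run_experiment, processed, atlas,
        feature_kind=cl["feature_kind"], k=k_opt,
        n_trials=cl["n_trials"], seed=seed,
        train_fraction=cl["train_fraction"],
        regularization=cl["regularization"],
        n_replicates=cl["n_replicates"])
    results["classification"] = run
    results["classification_p_vs_chance"] = compare_to_chance(run)

    manifest = _write_outputs(results, outdir)
    results["manifest"] = manifest
    return results


def _write_outputs(results: dict, outdir: Path) -> dict:
    atlas = results["atlas"]
    capset = results["capset"]
    mask = atlas.analysis_mask
    files = {}

    capio.save_config(results["config"], outdir / "config.yaml")
    files["config"] = "config.yaml"
    results["curve"].to_frame().to_csv(outdir / "variance_curve.csv",
                                       index=False)
    files["variance_curve"] = "variance_curve.csv"
    labels_df = results["pool"].provenance.copy()
    labels_df["cap_id"] = results["solution"].labels
    labels_df.to_csv(outdir / "frame_labels.csv", index=False)
    files["frame_labels"] = "frame_labels.csv"
    results["metrics"].to_csv(outdir / "subject_cap_metrics.csv", index=False)
    files["subject_cap_metrics"] = "subject_cap_metrics.csv"
    results["roi_categories"].to_csv(outdir / "roi_seven_categories.csv",
                                     index=False)
    files["roi_categories"] = "roi_seven_categories.csv"
    results["comparisons"].to_csv(outdir / "group_comparisons.csv",
                                  index=False)
    files["group_comparisons"] = "group_comparisons.csv"
    for cap in capset:
        base = f"cap{cap.cap_id:02d}"
        capio.write_map(cap.combined, mask, outdir / f"{base}_combined.nii")
        files[f"{base}_combined"] = f"{base}_combined.nii"
        for g, gmap in cap.group_maps.items():
            if gmap is not None:
                capio.write_map(gmap, mask, outdir / f"{base}_{g}.nii")
                files[f"{base}_{g}"] = f"{base}_{g}.nii"
    run = results["classification"]
    pd.DataFrame({
        "trial": np.arange(len(run.real_accuracy)),
        "real_accuracy": run.real_accuracy,
        "chance_accuracy": run.chance_accuracy,
    }).to_csv(outdir / "classification_trials.csv", index=False)
    files["classification_trials"] = "classification_trials.csv"
    summary = run.summary()
    summary["p_vs_chance"] = results["classification_p_vs_chance"]
    summary["selected_k"] = int(results["curve"].selected_k)
    capio.save_json(summary, outdir / "classification_summary.json")
    files["classification_summary"] = "classification_summary.json"

    manifest = {
        "seed": results["config"]["seed"],
        "selected_k": int(results["curve"].selected_k),
        "outputs": {key: {"path": rel, "sha256": _sha256(outdir / rel)}
                    for key, rel in files.items()},
    }
    capio.save_json(manifest, outdir / "manifest.json")
    return manifest
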