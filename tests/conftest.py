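"""Shared fixtures: small synthetic cohorts and expensive simulation results.

Session-scoped so that cohort generation, clustering and the repeated-split
classification experiments run once and are reused by module tests and the
acceptance suite alike.
"""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from capdyn import (PreprocessingConfig, build_variance_curve,
                    concatenate_subjects, generate_atlas, generate_cohort,
                    kmeans_corr, make_model, preprocess_pipeline,
                    run_experiment)

TINY_ROIS = ["cingulate", "retrosplenial", "somatosensory", "motor"]


@pytest.fixture(scope="session")
def atlas_small():
    return generate_atlas((12, 12, 4))


@pytest.fixture(scope="session")
def atlas_tiny():
    return generate_atlas((10, 10, 3), roi_names=TINY_ROIS)


@pytest.fixture(scope="session")
def lownoise_cohort(atlas_small):
    """4+4 subjects, 150 frames, K_true=4, noise SD 0.3 (well-separated)."""
    model = make_model(atlas_small, k_true=4, n_frames=150,
                       group_sizes=(4, 4), noise_sd=0.3, mean_dwell=5.0,
                       seed=1)
    return generate_cohort(model, atlas_small, seed=1)


@pytest.fixture(scope="session")
def lownoise_pool(atlas_small, lownoise_cohort):
    """Preprocessed pool (temporal filter off — see docs/methods.md) with
    the hidden state labels aligned to the trimmed frames."""
    cfg = PreprocessingConfig(band=None)
    processed = [preprocess_pipeline(s, cfg) for s in lownoise_cohort.subjects]
    pool = concatenate_subjects(processed, atlas_small.analysis_mask)
    truth = np.concatenate([
        lownoise_cohort.state_sequences[s.subject_id][10:-10]
        for s in lownoise_cohort.subjects])
    return {"pool": pool, "truth": truth, "processed": processed}


@pytest.fixture(scope="session")
def recovery_result(lownoise_pool, lownoise_cohort):
    """Planted-K recovery: variance-curve selection and frame-label ARI."""
    pool = lownoise_pool["pool"]
    curve = build_variance_curve(pool, k_min=2, k_max=8, seed=0,
                                 n_replicates=3)
    solution = kmeans_corr(pool, lownoise_cohort.model.k_true, seed=0,
                           n_replicates=3)
    ari = adjusted_rand_score(lownoise_pool["truth"], solution.labels)
    return {"curve": curve, "selected_k": curve.selected_k,
            "k_true": lownoise_cohort.model.k_true, "ari": ari,
            "solution": solution}


@pytest.fixture(scope="session")
def null_run50(atlas_tiny):
    """50-trial spatial-feature experiment on an 18+19 cohort with no
    group effect — the chance-calibration workhorse."""
    model = make_model(atlas_tiny, k_true=4, n_frames=150,
                       group_sizes=(18, 19), noise_sd=1.0, seed=7)
    cohort = generate_cohort(model, atlas_tiny, seed=7)
    processed = [preprocess_pipeline(s) for s in cohort.subjects]
    return run_experiment(processed, atlas_tiny, feature_kind="spatial",
                          k=4, n_trials=50, seed=11)


@pytest.fixture(scope="session")
def effect_sweep(atlas_tiny):
    """Mean real accuracy across a 3-point planted amplitude-effect sweep."""
    runs = {}
    for eff in (0.0, 0.3, 0.6):
        model = make_model(atlas_tiny, k_true=4, n_frames=120,
                           group_sizes=(6, 6), noise_sd=1.0,
                           amplitude_effect=eff, seed=5)
        cohort = generate_cohort(model, atlas_tiny, seed=5)
        processed = [preprocess_pipeline(s, PreprocessingConfig(band=None))
                     for s in cohort.subjects]
        runs[eff] = run_experiment(processed, atlas_tiny,
                                   feature_kind="spatial", k=4,
                                   n_trials=10, seed=3)
    return runs


@pytest.fixture(scope="session")
def null_gcaps(atlas_tiny):
    """Training gCAPs (K=2) with significance masks from a small pool."""
    from capdyn import extract_training_gcaps
    model = make_model(atlas_tiny, k_true=2, n_frames=80, group_sizes=(3, 3),
                       noise_sd=1.0, seed=13)
    cohort = generate_cohort(model, atlas_tiny, seed=13)
    processed = [preprocess_pipeline(s, PreprocessingConfig(band=None))
                 for s in cohort.subjects]
    pool = concatenate_subjects(processed, atlas_tiny.analysis_mask)
    return extract_training_gcaps(pool, 2, seed=0, n_replicates=3), pool


@pytest.fixture(scope="session")
def bonferroni_fwer():
    """Family-wise error of the Bonferroni one-sample map on pure noise:
    fraction of 500 simulated families (10 occurrences x 200 voxels) with
    any rejection at alpha=0.01."""
    from capdyn import one_sample_t_map
    rng = np.random.default_rng(42)
    hits = 0
    for _ in range(500):
        res = one_sample_t_map(rng.normal(size=(10, 200)), alpha=0.01)
        hits += bool(res.significant.any())
    return hits / 500


@pytest.fixture(scope="session")
def fdr_null_rejection_fraction():
    """Fraction of 1000 null two-group simulations (m=50 voxels) in which
    the BH-FDR map rejects anything; ~q under the global null."""
    from capdyn import two_sample_t_map
    rng = np.random.default_rng(43)
    domain = np.ones(50, dtype=bool)
    hits = 0
    for _ in range(1000):
        res = two_sample_t_map(rng.normal(size=(10, 50)),
                               rng.normal(size=(10, 50)), domain, q=0.05)
        hits += bool(res.fdr_mask.any())
    return hits / 1000
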