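"""Leakage-free cross-validated genotype classification from CAP features.

The experiment repeats, over stratified 80/20 train/test splits of the
subjects, the full feature pipeline: group-level CAPs (gCAPs) are extracted
from the training subjects' frames only; every subject's frames are then
labelled by their best-correlated gCAP (correlation computed over that
gCAP's significantly activated voxels); subject-level CAPs and temporal
metrics follow from those labels. Feature vectors (temporal, spatial, or
ROI-pair functional connectivity) are z-scored within subject so that
relative rankings, not absolute values, drive the classifier — a regularized
multinomial logistic regression. Chance accuracy reuses the identical split
and features with class identities permuted across all subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import CapSet, FramePool, ImageSeries
from .extraction import concatenate_subjects, kmeans_corr, build_caps
from .metrics import (mean_duration, occurrence_percentage, one_sample_t_map)

FEATURE_KINDS = ("temporal", "spatial", "fc")


@dataclass
class SplitScheme:
    trial: int
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def stratified_split(subject_table: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0, trial: int = 0) -> SplitScheme:
    """Random genotype-stratified split: floor(fraction * n) per group train.

    With 18 + 19 subjects at 80% this gives 14 + 15 = 29 training and
    4 + 4 = 8 test subjects.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, sub in subject_table.groupby("group", sort=False):
        ids = sub["subject_id"].tolist()
        if len(ids) < 2:
            raise ValueError("each group needs >= 2 subjects")
        n_train = int(np.floor(train_fraction * len(ids)))
        if n_train == len(ids):
            raise ValueError("empty test stratum; lower train_fraction")
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return SplitScheme(trial=trial, train_ids=train, test_ids=test, seed=seed)


def extract_training_gcaps(train_pool: FramePool, k: int, seed: int = 0,
                           n_replicates: int = 2, max_iter: int = 100,
                           alpha: float = 0.01,
                           groups: Sequence[str] = ("WT", "HET")) -> CapSet:
    """Cluster the training pool and attach combined one-sample masks.

    K is fixed to the study-level optimum for the condition; the gCAPs and
    their significance masks depend on training subjects only, which is what
    makes downstream evaluation leakage-free.
    """
    solution = kmeans_corr(train_pool, k, seed=seed,
                           n_replicates=n_replicates, max_iter=max_iter)
    gcaps = build_caps(train_pool, solution, groups=groups)
    for cap in gcaps:
        members = solution.labels == cap.cap_id
        cap.significance = {"combined": one_sample_t_map(
            train_pool.frames[members], alpha=alpha)}
    return gcaps


def assign_frames_to_gcaps(frames: np.ndarray, gcaps: CapSet) -> np.ndarray:
    """Label each frame with its best-correlated gCAP (1..K).

    Correlation is computed over each gCAP's significantly (de)activated
    voxels only. Exact ties go to the lowest CAP index (argmax convention).
    """
    frames = np.asarray(frames, dtype=float)
    corrs = np.empty((frames.shape[0], gcaps.k))
    for j, cap in enumerate(gcaps):
        mask = cap.significance["combined"].significant
        if mask.sum() < 3:
            raise ValueError(
                f"gCAP {cap.cap_id} has {int(mask.sum())} significant voxels "
                "(< 3); cannot correlate frames against it")
        sub = frames[:, mask]
        tmpl = cap.combined[mask]
        sub_c = sub - sub.mean(axis=1, keepdims=True)
        tmpl_c = tmpl - tmpl.mean()
        denom = np.linalg.norm(sub_c, axis=1) * np.linalg.norm(tmpl_c)
        denom = np.where(denom < 1e-12, 1.0, denom)
        corrs[:, j] = (sub_c @ tmpl_c) / denom
    return corrs.argmax(axis=1) + 1


def build_subject_caps(frames: np.ndarray, labels: np.ndarray,
                       k: int) -> dict:
    """Voxel-wise mean of a subject's frames per assigned label.

    Returns ``cap_id -> map`` with ``None`` for labels that never occur
    (flagged missing, not zero-filled).
    """
    out = {}
    for cap_id in range(1, k + 1):
        sel = labels == cap_id
        out[cap_id] = frames[sel].mean(axis=0) if sel.any() else None
    return out


def zscore_within_subject(vector: np.ndarray) -> np.ndarray:
    """Standardise one subject's feature vector; constant vectors become 0."""
    v = np.asarray(vector, dtype=float)
    sd = v.std()
    if sd < 1e-12:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def temporal_features(labels_by_subject: dict, k: int, tr: float) -> dict:
    """Per subject, the 2K vector (mean duration, occurrence %) per CAP.

    A CAP a subject never visits contributes duration 0 and occurrence 0
    before z-scoring (absence ranked worst, not treated as missing data).
    """
    feats = {}
    for sid, labels in labels_by_subject.items():
        vec = []
        for cap_id in range(1, k + 1):
            dur, _ = mean_duration(labels, cap_id, tr)
            vec.append(0.0 if np.isnan(dur) else dur)
            vec.append(occurrence_percentage(labels, cap_id))
        feats[sid] = zscore_within_subject(np.array(vec))
    return feats


def spatial_features(subject_caps_by_subject: dict, gcaps: CapSet) -> dict:
    """Per subject, subject-CAP intensities at each gCAP's significant voxels.

    Blocks are concatenated over CAPs (dimension = sum of significant voxel
    counts); a missing subject CAP contributes a zero block. The vector is
    z-scored within subject.
    """
    masks = {cap.cap_id: cap.significance["combined"].significant
             for cap in gcaps}
    feats = {}
    for sid, caps in subject_caps_by_subject.items():
        blocks = []
        for cap_id in range(1, gcaps.k + 1):
            m = masks[cap_id]
            cap_map = caps.get(cap_id)
            blocks.append(cap_map[m] if cap_map is not None
                          else np.zeros(int(m.sum())))
        feats[sid] = zscore_within_subject(np.concatenate(blocks))
    return feats


def fc_features(series: ImageSeries, atlas, region_labels: Sequence[int]
                ) -> np.ndarray:
    """Upper-triangle ROI-pair Pearson correlations of one subject.

    ROI time courses are voxel means within each atlas region; n regions
    give n(n-1)/2 features. The vector is z-scored within subject.
    """
    flat_labels = atlas.labels[series.mask]
    courses = []
    for lab in region_labels:
        sel = flat_labels == lab
        if not sel.any():
            raise ValueError(f"region label {lab} is empty in this mask")
        courses.append(series.data[:, sel].mean(axis=1))
    tc = np.asarray(courses)
    sd = tc.std(axis=1)
    tc = tc - tc.mean(axis=1, keepdims=True)
    tc[sd > 1e-12] /= np.linalg.norm(tc[sd > 1e-12], axis=1, keepdims=True)
    r = tc @ tc.T
    iu = np.triu_indices(len(region_labels), k=1)
    return zscore_within_subject(r[iu])


def train_mlr(features: np.ndarray, labels: Sequence[str],
              regularization: float = 10.0) -> LogisticRegression:
    """Fit an L2-regularized (multinomial) logistic regression.

    ``regularization`` is the penalty weight lambda; scikit-learn's C is its
    inverse. Two-class problems are the binomial special case of the
    multinomial model.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain >= 2 classes")
    model = LogisticRegression(C=1.0 / regularization, solver="lbfgs",
                               max_iter=2000)  # default penalty is L2
    model.fit(np.asarray(features), y)
    return model


@dataclass
class ClassificationRun:
    feature_kind: str
    k: int
    real_accuracy: np.ndarray
    chance_accuracy: np.ndarray
    splits: list
    seed: int
    regularization: float = 10.0

    def summary(self) -> dict:
        real, chance = self.real_accuracy, self.chance_accuracy
        return {
            "feature_kind": self.feature_kind, "k": self.k,
            "n_trials": len(real),
            "real_mean": float(real.mean()),
            "real_sem": float(real.std(ddof=1) / np.sqrt(len(real))),
            "real_median": float(np.median(real)),
            "chance_mean": float(chance.mean()),
            "chance_sem": float(chance.std(ddof=1) / np.sqrt(len(chance))),
            "chance_median": float(np.median(chance)),
        }


def _subject_features(series_list, atlas, gcaps, feature_kind, tr,
                      fc_regions):
    """Feature vector per subject for one trial's gCAPs."""
    if feature_kind == "fc":
        return {s.subject_id: fc_features(s, atlas, fc_regions)
                for s in series_list}
    analysis_cols = {id(s): atlas.analysis_mask[s.mask] for s in series_list}
    labels_by_subject, caps_by_subject = {}, {}
    for s in series_list:
        frames = s.data[:, analysis_cols[id(s)]]
        labels = assign_frames_to_gcaps(frames, gcaps)
        labels_by_subject[s.subject_id] = labels
        if feature_kind == "spatial":
            caps_by_subject[s.subject_id] = build_subject_caps(
                frames, labels, gcaps.k)
    if feature_kind == "temporal":
        return temporal_features(labels_by_subject, gcaps.k, tr)
    if feature_kind == "spatial":
        return spatial_features(caps_by_subject, gcaps)
    raise ValueError(f"unknown feature kind {feature_kind!r}")


def run_experiment(series_list: Sequence[ImageSeries], atlas,
                   feature_kind: str = "spatial", k: int = 4,
                   n_trials: int = 50, seed: int = 0,
                   train_fraction: float = 0.8, regularization: float = 10.0,
                   n_replicates: int = 2, fc_regions: Optional[Sequence[int]] = None,
                   shuffle_labels: bool = False) -> ClassificationRun:
    """The full repeated-split classification experiment.

    Per trial: stratified split -> gCAPs from training frames only ->
    features for all subjects -> fit on train, accuracy on test. The chance
    accuracy reuses the identical split and features with a full permutation
    of class identities across all subjects. With ``shuffle_labels=True``
    the "real" arm itself runs on permuted labels (a null experiment).
    """
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
    if feature_kind == "fc" and fc_regions is None:
        fc_regions = [lab for lab in atlas.roi_names
                      if lab != atlas.excluded_label]
    table = pd.DataFrame({
        "subject_id": [s.subject_id for s in series_list],
        "group": [s.group for s in series_list]})
    true_label = dict(zip(table["subject_id"], table["group"]))
    tr = series_list[0].tr
    master = np.random.default_rng(seed)
    real_acc, chance_acc, splits = [], [], []
    for trial in range(n_trials):
        trial_seed = int(master.integers(2 ** 31))
        split = stratified_split(table, train_fraction, seed=trial_seed,
                                 trial=trial)
        train_series = [s for s in series_list
                        if s.subject_id in split.train_ids]
        if feature_kind == "fc":
            gcaps = None
        else:
            train_pool = concatenate_subjects(train_series,
                                              atlas.analysis_mask)
            gcaps = extract_training_gcaps(train_pool, k, seed=trial_seed,
                                           n_replicates=n_replicates)
        feats = _subject_features(series_list, atlas, gcaps, feature_kind,
                                  tr, fc_regions)
        rng = np.random.default_rng(trial_seed + 1)
        all_ids = table["subject_id"].tolist()
        perm = rng.permutation(len(all_ids))
        shuffled = {sid: true_label[all_ids[j]]
                    for sid, j in zip(all_ids, perm)}
        label_map = shuffled if shuffle_labels else true_label

        def _accuracy(labels_of):
            x_tr = np.array([feats[s] for s in split.train_ids])
            y_tr = np.array([labels_of[s] for s in split.train_ids])
            x_te = np.array([feats[s] for s in split.test_ids])
            y_te = np.array([labels_of[s] for s in split.test_ids])
            if len(np.unique(y_tr)) < 2:
                return float(np.mean(y_te == y_tr[0]))
            model = train_mlr(x_tr, y_tr, regularization)
            return float(np.mean(model.predict(x_te) == y_te))

        real_acc.append(_accuracy(label_map))
        chance_map = {sid: true_label[all_ids[j]]
                      for sid, j in zip(all_ids,
                                        np.random.default_rng(
                                            trial_seed + 2).permutation(
                                                len(all_ids)))}
        chance_acc.append(_accuracy(chance_map))
        splits.append(split)
    return ClassificationRun(
        feature_kind=feature_kind, k=k, real_accuracy=np.array(real_acc),
        chance_accuracy=np.array(chance_acc), splits=splits, seed=seed,
        regularization=regularization)


def compare_to_chance(run: ClassificationRun) -> float:
    """Two-sided Wilcoxon signed-rank p for paired (real - chance) accuracies."""
    diff = run.real_accuracy - run.chance_accuracy
    if np.allclose(diff, 0.0):
        return 1.0
    _, p = stats.wilcoxon(run.real_accuracy, run.chance_accuracy)
    return float(p)


def compare_across_conditions(accuracies_by_condition: dict) -> dict:
    """One-way ANOVA plus Tukey-Kramer post-hoc across condition accuracies.

    Degrees of freedom are computed from the supplied arrays
    (df_between = g - 1, df_within = N - g).
    """
    names = list(accuracies_by_condition)
    arrays = [np.asarray(accuracies_by_condition[n], dtype=float)
              for n in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 conditions with >= 2 values each")
    if all(a.std() < 1e-15 for a in arrays):
        raise ValueError("degenerate (zero-variance) accuracy arrays")
    f, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * a.size for n, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels)
    return {
        "f": float(f), "p": float(p),
        "df_between": len(arrays) - 1,
        "df_within": int(values.size - len(arrays)),
        "tukey": pd.DataFrame(tukey.summary().data[1:],
                              columns=tukey.summary().data[0]),
    }


def two_sample_accuracy_test(acc_a: np.ndarray, acc_b: np.ndarray) -> dict:
    """Pooled two-sample t between two conditions' accuracy arrays."""
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p), "df": int(a.size + b.size - 2)}
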