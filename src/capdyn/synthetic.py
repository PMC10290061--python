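"""Synthetic state-switching BOLD cohorts with known ground truth.

The generator emulates a two-group resting-state fMRI study: each subject's
brain cycles through K hidden activation states organised as anti-correlated
spatial pattern pairs (a default-mode-like network versus a lateral cortical
network, and further pairs). The hidden state process is a discrete-time
Markov chain whose self-transition probability encodes a geometric dwell-time
distribution; group effects enter as dwell-mean differences and ROI-wise
amplitude scaling. Observed frames are the state's spatial pattern (scaled by
the subject's group amplitude) plus Gaussian noise.

Every quantity the downstream pipeline estimates — number of states, frame
labels, dwell times, occurrence rates, group differences — is therefore known
exactly, which is what makes the pipeline testable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ImageSeries

#: The 14 bilateral cortical/sub-cortical regions used for reporting, plus a
#: cerebellum-like region that is excluded from CAP analysis.
DEFAULT_ROI_NAMES = (
    "retrosplenial", "visual", "motor", "cingulate", "olfactory_bulb",
    "somatosensory", "auditory", "hippocampus", "frontal_association",
    "orbital", "caudate_putamen", "thalamus", "rhinal", "piriform",
)
EXCLUDED_ROI = "cerebellum"

#: Default-mode-like vs lateral-cortical membership used for the first
#: (DMLN/LCN) pattern pair and for group amplitude effects.
DMLN_ROIS = ("cingulate", "retrosplenial", "orbital", "visual",
             "hippocampus", "rhinal")
LCN_ROIS = ("somatosensory", "motor", "frontal_association", "caudate_putamen")


class AtlasError(ValueError):
    pass


@dataclass
class SyntheticAtlas:
    """Integer-labelled ROI parcellation on a small voxel grid.

    ``labels`` assigns every voxel an integer (0 = background). Bilateral
    ROIs get separate left/right labels. ``analysis_mask`` is the brain mask
    minus the excluded (cerebellum-like) region.
    """

    grid_dims: tuple
    labels: np.ndarray
    roi_names: dict  # label -> name
    brain_mask: np.ndarray
    analysis_mask: np.ndarray
    excluded_label: int

    def label_of(self, name: str) -> int:
        for lab, nm in self.roi_names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def roi_voxels(self, label: int, mask: np.ndarray | None = None) -> np.ndarray:
        """Column indices (within ``mask``, default brain mask) of one ROI."""
        mask = self.brain_mask if mask is None else mask
        flat = self.labels[mask]
        return np.flatnonzero(flat == label)

    def validate(self, min_report_voxels: int = 30) -> None:
        for lab, nm in self.roi_names.items():
            n = int(np.count_nonzero(self.labels == lab))
            if n < 1:
                raise AtlasError(f"ROI '{nm}' (label {lab}) has no voxels")
            if lab != self.excluded_label and n <= min_report_voxels:
                warnings.warn(
                    f"ROI '{nm}' has only {n} voxels "
                    f"(<= {min_report_voxels}); too small for reporting")
        if np.any(self.analysis_mask & ~self.brain_mask):
            raise AtlasError("analysis_mask must be a subset of brain_mask")


def generate_atlas(grid_dims=(20, 20, 6), roi_names=None, seed=0,
                   roi_voxels=None, excluded_fraction=0.15) -> SyntheticAtlas:
    """Build a deterministic bilateral parcellation of a voxel grid.

    By default the posterior ``excluded_fraction`` of the grid (along y)
    becomes the cerebellum-like excluded region; the rest is split into left
    and right hemispheres along x, and each hemisphere is tiled by the named
    ROIs as contiguous, equal-sized C-order chunks.

    Parameters
    ----------
    roi_names : sequence of str, optional
        Bilateral ROI names; each yields a ``_L`` and ``_R`` label. The
        excluded region is always appended. At least 3 names are required
        (>= 4 ROIs including the excluded one).
    roi_voxels : dict, optional
        Explicit ``name -> list of (x, y, z)`` assignments overriding the
        tiling; overlapping claims raise :class:`AtlasError` naming the
        colliding labels.
    seed : int
        Accepted for interface symmetry; the default tiling is fully
        deterministic so the seed does not influence the layout.
    """
    del seed  # layout is deterministic
    grid_dims = tuple(int(d) for d in grid_dims)
    if any(d <= 0 for d in grid_dims):
        raise AtlasError("grid_dims must be positive")
    names = list(roi_names) if roi_names is not None else list(DEFAULT_ROI_NAMES)
    if len(names) < 3:
        raise AtlasError("need at least 3 bilateral ROI names "
                         "(>= 4 ROIs including the excluded region)")

    labels = np.zeros(grid_dims, dtype=np.int32)
    full_names = {}
    for i, nm in enumerate(names):
        full_names[2 * i + 1] = f"{nm}_L"
        full_names[2 * i + 2] = f"{nm}_R"
    excluded_label = 2 * len(names) + 1
    full_names[excluded_label] = EXCLUDED_ROI

    if roi_voxels is not None:
        name_to_label = {v: k for k, v in full_names.items()}
        claimed = {}
        for nm, voxels in roi_voxels.items():
            lab = name_to_label.get(nm)
            if lab is None:
                raise AtlasError(f"unknown ROI name '{nm}'")
            for vox in voxels:
                vox = tuple(int(c) for c in vox)
                if vox in claimed:
                    raise AtlasError(
                        f"voxel {vox} claimed by both "
                        f"'{full_names[claimed[vox]]}' and '{full_names[lab]}'")
                claimed[vox] = lab
                labels[vox] = lab
    else:
        nx, ny, _ = grid_dims
        cb_rows = max(1, int(round(excluded_fraction * ny)))
        cerebellum = np.zeros(grid_dims, dtype=bool)
        cerebellum[:, ny - cb_rows:, :] = True
        labels[cerebellum] = excluded_label
        for side, (x0, x1) in enumerate(((0, nx // 2), (nx // 2, nx))):
            hemi = np.zeros(grid_dims, dtype=bool)
            hemi[x0:x1, : ny - cb_rows, :] = True
            coords = np.argwhere(hemi)  # C order
            chunks = np.array_split(coords, len(names))
            for i, chunk in enumerate(chunks):
                lab = 2 * i + 1 + side
                labels[tuple(chunk.T)] = lab

    brain_mask = labels > 0
    analysis_mask = brain_mask & (labels != excluded_label)
    atlas = SyntheticAtlas(grid_dims, labels, full_names, brain_mask,
                           analysis_mask, excluded_label)
    for lab, nm in full_names.items():
        if roi_voxels is None and not np.any(labels == lab):
            raise AtlasError(f"ROI '{nm}' received no voxels on this grid")
    return atlas


@dataclass
class GroundTruthModel:
    """Fully specified generative model for a synthetic cohort.

    ``patterns`` is K x n_brain_voxels (zero over the excluded region),
    constructed as anti-correlated pairs. ``dwell_mean_frames`` and
    ``occurrence_bias`` are K x 2 arrays (columns = WT, HET).
    ``amplitude_scale`` is n_brain_voxels x 2, a multiplicative per-voxel
    group effect derived from ROI-wise scaling factors.
    """

    k_true: int
    patterns: np.ndarray
    dwell_mean_frames: np.ndarray
    occurrence_bias: np.ndarray
    amplitude_scale: np.ndarray
    noise_sd: float
    tr: float = 0.5
    n_frames: int = 1200
    group_sizes: tuple = (18, 19)
    groups: tuple = ("WT", "HET")
    ar1: float = 0.0

    def validate(self) -> None:
        if np.any(self.dwell_mean_frames < 1):
            raise ValueError("dwell_mean_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group_sizes must be positive")
        if self.patterns.shape[0] != self.k_true:
            raise ValueError("patterns must have k_true rows")

    def transition_matrix(self, group_index: int) -> np.ndarray:
        """Markov transition matrix for one group.

        Self-transition p_s = 1 - 1/dwell_mean(s); the leave mass is split
        across the other states proportionally to their occurrence bias, so
        dwell times are geometric with the requested means.
        """
        k = self.k_true
        dwell = self.dwell_mean_frames[:, group_index]
        bias = self.occurrence_bias[:, group_index]
        t = np.zeros((k, k))
        for s in range(k):
            stay = 1.0 - 1.0 / dwell[s]
            others = np.delete(np.arange(k), s)
            w = bias[others]
            t[s, s] = stay
            t[s, others] = (1.0 - stay) * w / w.sum()
        return t

    def stationary_distribution(self, group_index: int) -> np.ndarray:
        t = self.transition_matrix(group_index)
        vals, vecs = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def make_patterns(atlas: SyntheticAtlas, k_true: int, seed: int = 0,
                  within_roi_gradient: float = 0.15) -> np.ndarray:
    """Construct K anti-correlated pattern pairs over the brain mask.

    Pair 0 is the DMLN/LCN pair: default-mode-like ROIs co-activate while
    lateral-cortical ROIs co-deactivate, and vice versa. Further pairs get
    seeded random ROI-wise coefficients. Each ROI also carries a mild linear
    within-ROI gradient so patterns are not piecewise constant. Patterns in
    a pair are exact negations, hence spatial correlation -1 on the analysis
    mask. The excluded region stays at zero.
    """
    if k_true % 2 != 0:
        raise ValueError("k_true must be even (states come in pairs)")
    rng = np.random.default_rng(seed)
    n_vox = int(np.count_nonzero(atlas.brain_mask))
    flat_labels = atlas.labels[atlas.brain_mask]
    patterns = np.zeros((k_true, n_vox))

    roi_labels = [lab for lab in atlas.roi_names if lab != atlas.excluded_label]
    base_name = {lab: atlas.roi_names[lab].rsplit("_", 1)[0] for lab in roi_labels}

    for pair in range(k_true // 2):
        coef = {}
        for lab in roi_labels:
            nm = base_name[lab]
            if pair == 0:
                if nm in DMLN_ROIS:
                    coef[lab] = 1.0
                elif nm in LCN_ROIS:
                    coef[lab] = -1.0
                else:
                    coef[lab] = 0.25
            else:
                coef[lab] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
        vec = np.zeros(n_vox)
        for lab in roi_labels:
            idx = np.flatnonzero(flat_labels == lab)
            ramp = np.linspace(-1.0, 1.0, idx.size)
            vec[idx] = coef[lab] * (1.0 + within_roi_gradient * ramp)
        # zero spatial mean: activation is a deviation pattern, so the
        # global (whole-brain mean) signal carries no state information
        inside = vec != 0
        vec[inside] -= vec[inside].mean()
        patterns[2 * pair] = vec
        patterns[2 * pair + 1] = -vec
    return patterns


def make_model(atlas: SyntheticAtlas, *, k_true: int = 4, n_frames: int = 1200,
               tr: float = 0.5, group_sizes=(18, 19), mean_dwell: float = 5.0,
               dwell_effect: float = 0.0, amplitude_effect: float = 0.0,
               noise_sd: float = 1.0, ar1: float = 0.0,
               seed: int = 0) -> GroundTruthModel:
    """Assemble a :class:`GroundTruthModel` for the study conditions.

    ``dwell_effect`` shortens the HET dwell mean of the DMLN/LCN pair
    (states 1 and 2) by that fraction, mirroring a reduced state duration in
    the mutant group. ``amplitude_effect`` multiplies HET activation in the
    default-mode-like ROIs by ``1 - amplitude_effect``, mirroring reduced
    activation magnitude. Both default to 0 (null cohort).
    """
    patterns = make_patterns(atlas, k_true, seed=seed)
    dwell = np.full((k_true, 2), float(mean_dwell))
    dwell[0, 1] *= (1.0 - dwell_effect)
    dwell[1, 1] *= (1.0 - dwell_effect)
    bias = np.ones((k_true, 2))

    n_vox = int(np.count_nonzero(atlas.brain_mask))
    amp = np.ones((n_vox, 2))
    if amplitude_effect != 0.0:
        flat_labels = atlas.labels[atlas.brain_mask]
        for lab, nm in atlas.roi_names.items():
            if nm.rsplit("_", 1)[0] in DMLN_ROIS:
                amp[flat_labels == lab, 1] = 1.0 - amplitude_effect
    model = GroundTruthModel(
        k_true=k_true, patterns=patterns, dwell_mean_frames=dwell,
        occurrence_bias=bias, amplitude_scale=amp, noise_sd=noise_sd,
        tr=tr, n_frames=int(n_frames), group_sizes=tuple(group_sizes), ar1=ar1)
    model.validate()
    return model


@dataclass
class SyntheticCohort:
    subjects: list  # of ImageSeries
    state_sequences: dict  # subject_id -> ndarray of 0-based state indices
    model: GroundTruthModel
    atlas: SyntheticAtlas
    seed: int = 0

    @property
    def subject_table(self):
        import pandas as pd
        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.subjects],
            "group": [s.group for s in self.subjects],
        })


def simulate_states(transition: np.ndarray, n_frames: int,
                    rng: np.random.Generator,
                    initial: np.ndarray | None = None) -> np.ndarray:
    """Sample a state path of length ``n_frames`` from a Markov chain."""
    k = transition.shape[0]
    if initial is None:
        initial = np.full(k, 1.0 / k)
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = rng.choice(k, p=initial)
    # cumulative rows let us invert uniform draws without per-step choice()
    cum = np.cumsum(transition, axis=1)
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def generate_cohort(model: GroundTruthModel, atlas: SyntheticAtlas,
                    seed: int = 0) -> SyntheticCohort:
    """Simulate every subject's hidden state path and noisy BOLD frames.

    Frame t of a subject in group g equals
    ``patterns[state_t] * amplitude_scale[:, g] + noise`` with i.i.d.
    Gaussian noise of SD ``noise_sd`` (optionally AR(1) over time with
    coefficient ``model.ar1``). With ``noise_sd = 0`` frames reproduce the
    scaled patterns exactly.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    subjects, sequences = [], {}
    for gi, (gname, gsize) in enumerate(zip(model.groups, model.group_sizes)):
        transition = model.transition_matrix(gi)
        stationary = model.stationary_distribution(gi)
        amp = model.amplitude_scale[:, gi]
        for si in range(gsize):
            sid = f"{gname}{si + 1:02d}"
            states = simulate_states(transition, model.n_frames, rng,
                                     initial=stationary)
            clean = model.patterns[states] * amp[None, :]
            if model.noise_sd > 0:
                noise = rng.normal(0.0, model.noise_sd,
                                   size=clean.shape)
                if model.ar1 > 0:
                    for t in range(1, noise.shape[0]):
                        noise[t] = model.ar1 * noise[t - 1] + \
                            np.sqrt(1 - model.ar1 ** 2) * noise[t]
                data = clean + noise
            else:
                data = clean
            subjects.append(ImageSeries(
                data=data, tr=model.tr, mask=atlas.brain_mask,
                subject_id=sid, group=gname, mask_id="brain"))
            sequences[sid] = states
    return SyntheticCohort(subjects, sequences, model, atlas, seed)
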