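"""Temporal and spatial CAP metrics.

Temporal metrics are per subject: the occurrence percentage of a CAP (share
of the subject's frames assigned to it) and its duration (mean length, in
consecutive frames, of the maximal runs of that CAP in the subject's label
sequence; convertible to seconds via TR).

Spatial statistics are voxel-wise and run across the occurrences of a CAP in
the concatenated group image-series: a one-sample two-tailed t-test against
zero activation with Bonferroni correction splits voxels into significantly
activated and deactivated sets; a pooled-variance two-sample t-test with
Benjamini-Hochberg FDR correction, restricted to voxels significant in
either group, maps genotype differences. The seven-category ROI table
summarises both maps per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CapSet, FramePool


# ---------------------------------------------------------------- temporal

def run_lengths(labels: np.ndarray, cap_id: int) -> np.ndarray:
    """Lengths of maximal runs of ``cap_id`` in a label sequence.

    Runs touching either end of the sequence count in full (no censoring).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    is_cap = np.concatenate(([0], (labels == cap_id).astype(int), [0]))
    edges = np.diff(is_cap)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return stops - starts


def occurrence_percentage(labels: np.ndarray, cap_id: int,
                          n_caps: Optional[int] = None) -> float:
    """100 * (frames assigned to ``cap_id``) / (total frames).

    ``n_caps`` bounds the valid CAP ids; without it, ids up to the largest
    observed label are accepted (a CAP the subject never visits is 0%, an
    id outside the solution is an error).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    bound = int(n_caps) if n_caps is not None else int(labels.max())
    if not 1 <= cap_id <= bound:
        raise ValueError(f"unknown cap_id {cap_id} (valid: 1..{bound})")
    return 100.0 * float(np.count_nonzero(labels == cap_id)) / labels.size


def mean_duration(labels: np.ndarray, cap_id: int, tr: float) -> tuple:
    """(mean run length in frames, in seconds); NaN if the CAP never occurs."""
    runs = run_lengths(labels, cap_id)
    if runs.size == 0:
        return float("nan"), float("nan")
    frames = float(runs.mean())
    return frames, frames * tr


def subject_cap_metrics(pool: FramePool, labels: np.ndarray, k: int,
                        tr: float) -> pd.DataFrame:
    """Per-subject temporal metrics for every CAP.

    Splits the pooled frame labels back into per-subject sequences via the
    pool's provenance and returns a tidy table with one row per
    (subject, CAP): occurrence percentage, mean duration in frames and
    seconds, and the number of runs.
    """
    rows = []
    prov = pool.provenance
    for sid, idx in prov.groupby("subject_id", sort=False).groups.items():
        seq = labels[np.asarray(idx)]
        group = prov.loc[idx[0], "group"]
        for cap_id in range(1, k + 1):
            runs = run_lengths(seq, cap_id)
            dur_f, dur_s = mean_duration(seq, cap_id, tr)
            rows.append({
                "subject_id": sid, "group": group, "cap_id": cap_id,
                "occurrence_pct": occurrence_percentage(seq, cap_id,
                                                        n_caps=k),
                "mean_duration_frames": dur_f,
                "mean_duration_seconds": dur_s,
                "n_runs": int(runs.size),
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- spatial

@dataclass
class TMapResult:
    t: np.ndarray
    p: np.ndarray
    activated: np.ndarray      # significant & positive mean
    deactivated: np.ndarray    # significant & negative mean
    degenerate: np.ndarray     # zero-variance voxels, excluded from masks
    alpha: float
    n_tests: int

    @property
    def significant(self) -> np.ndarray:
        return self.activated | self.deactivated


def one_sample_t_map(frames_of_cap: np.ndarray, alpha: float = 0.01,
                     n_tests: Optional[int] = None) -> TMapResult:
    """Voxel-wise one-sample two-tailed t-test with Bonferroni correction.

    ``frames_of_cap`` is occurrences x voxels. The Bonferroni threshold is
    ``alpha / n_tests`` with ``n_tests`` defaulting to the number of voxels
    tested (the analysis-mask size).
    """
    x = np.asarray(frames_of_cap, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 occurrences (rows)")
    m = x.shape[1]
    n_tests = m if n_tests is None else int(n_tests)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd < 1e-12
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # constant voxels are flagged below; silence scipy's precision
        # warning for them
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_1samp(x, 0.0, axis=0)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    sig = np.zeros(m, dtype=bool)
    ok = ~degenerate
    sig[ok] = p[ok] < alpha / n_tests
    mean = x.mean(axis=0)
    return TMapResult(t=t, p=p, activated=sig & (mean > 0),
                      deactivated=sig & (mean < 0), degenerate=degenerate,
                      alpha=alpha, n_tests=n_tests)


def benjamini_hochberg(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class TwoSampleResult:
    t: np.ndarray            # over domain voxels; sign = WT mean - HET mean
    p: np.ndarray
    fdr_mask: np.ndarray     # rejected at BH-FDR q, within the domain
    domain: np.ndarray       # boolean over all voxels
    degenerate: np.ndarray
    df: int
    q: float
    sign_convention: str = ("positive t: lower activation magnitude in HET "
                            "where WT-activated")


def two_sample_t_map(frames_wt: np.ndarray, frames_het: np.ndarray,
                     domain_mask: np.ndarray, q: float = 0.05
                     ) -> TwoSampleResult:
    """Pooled-variance two-sample t per voxel with BH-FDR over the domain.

    The domain is the union of voxels significantly (de)activated in either
    group's one-sample map; FDR correction counts only those voxels.
    """
    a = np.asarray(frames_wt, dtype=float)
    b = np.asarray(frames_het, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need >= 2 occurrences")
    domain = np.asarray(domain_mask, dtype=bool)
    m = a.shape[1]
    t_full = np.full(m, np.nan)
    p_full = np.full(m, np.nan)
    degenerate = np.zeros(m, dtype=bool)
    if domain.any():
        av, bv = a[:, domain], b[:, domain]
        pooled_sd = np.sqrt(((av.shape[0] - 1) * av.var(axis=0, ddof=1) +
                             (bv.shape[0] - 1) * bv.var(axis=0, ddof=1)))
        deg = pooled_sd < 1e-12
        t, p = stats.ttest_ind(av, bv, axis=0, equal_var=True)
        t[deg], p[deg] = np.nan, np.nan
        t_full[domain], p_full[domain] = t, p
        degenerate[domain] = deg
    fdr_mask = np.zeros(m, dtype=bool)
    testable = domain & ~degenerate & np.isfinite(p_full)
    if testable.any():
        fdr_mask[testable] = benjamini_hochberg(p_full[testable], q)
    df = a.shape[0] + b.shape[0] - 2
    return TwoSampleResult(t=t_full, p=p_full, fdr_mask=fdr_mask,
                           domain=domain, degenerate=degenerate, df=df, q=q)


def significance_for_caps(pool: FramePool, capset: CapSet, alpha: float = 0.01,
                          q: float = 0.05,
                          groups: Sequence[str] = ("WT", "HET")) -> CapSet:
    """Fill every CAP's significance maps from its pooled occurrences.

    Per CAP: one-sample Bonferroni maps for the combined series and each
    group's portion, then the two-sample WT-HET map over the union of
    group-significant voxels.
    """
    labels = capset.solution.labels
    grp = pool.provenance["group"].to_numpy()
    for cap in capset:
        members = labels == cap.cap_id
        sig = {"combined": one_sample_t_map(pool.frames[members],
                                            alpha=alpha)}
        for g in groups:
            sel = members & (grp == g)
            sig[g] = one_sample_t_map(pool.frames[sel], alpha=alpha) \
                if sel.sum() >= 2 else None
        if sig[groups[0]] is not None and sig[groups[1]] is not None:
            domain = sig[groups[0]].significant | sig[groups[1]].significant
            sig["two_sample"] = two_sample_t_map(
                pool.frames[members & (grp == groups[0])],
                pool.frames[members & (grp == groups[1])], domain, q=q)
        else:
            sig["two_sample"] = None
        cap.significance = sig
    return capset


# --------------------------------------------------------------- ROI level

SEVEN_CATEGORIES = ("a", "b", "c", "d", "e", "f", "g")


def roi_seven_categories(capset: CapSet, atlas, cap_id: int,
                         groups: Sequence[str] = ("WT", "HET")
                         ) -> pd.DataFrame:
    """Per-ROI percentages of voxels in the seven significance categories.

    Categories (percentages sum to 100 per ROI):
    a) activated (in either group) and higher magnitude in the first group,
    b) activated, no significant group difference,
    c) activated and higher magnitude in the second group,
    d/e/f) the same three for deactivated voxels,
    g) not significantly (de)activated in either group.
    For activated voxels a positive two-sample t (WT minus HET) means the
    WT magnitude is higher; for deactivated voxels the sign flips.
    """
    cap = capset[cap_id]
    sig = cap.significance
    if not sig or sig.get(groups[0]) is None or sig.get(groups[1]) is None:
        raise ValueError("significance maps must be computed first")
    act = sig[groups[0]].activated | sig[groups[1]].activated
    deact = (sig[groups[0]].deactivated | sig[groups[1]].deactivated) & ~act
    two = sig["two_sample"]
    diff = two.fdr_mask if two is not None else np.zeros(act.size, dtype=bool)
    tval = two.t if two is not None else np.zeros(act.size)

    flat_labels = atlas.labels[atlas.brain_mask]
    if capset.mask_id == "analysis":
        flat_labels = flat_labels[atlas.analysis_mask[atlas.brain_mask]]
    rows = []
    for lab, name in atlas.roi_names.items():
        if lab == atlas.excluded_label:
            continue
        in_roi = flat_labels == lab
        n = int(in_roi.sum())
        if n == 0:
            rows.append({"roi": name, "cap_id": cap_id, "n_voxels": 0,
                         "flagged_empty": True,
                         **{c: float("nan") for c in SEVEN_CATEGORIES}})
            continue
        wt_higher = diff & (tval > 0)
        het_higher = diff & (tval < 0)
        cats = {
            "a": act & wt_higher, "b": act & ~diff, "c": act & het_higher,
            "d": deact & het_higher, "e": deact & ~diff,
            "f": deact & wt_higher, "g": ~act & ~deact,
        }
        rows.append({"roi": name, "cap_id": cap_id, "n_voxels": n,
                     "flagged_empty": False,
                     **{c: 100.0 * int((m & in_roi).sum()) / n
                        for c, m in cats.items()}})
    return pd.DataFrame(rows)


def roi_mean_activation(cap_map: np.ndarray, atlas, roi_label: int,
                        mask_id: str = "analysis") -> float:
    """Mean CAP value over one ROI's voxels."""
    flat_labels = atlas.labels[atlas.brain_mask]
    if mask_id == "analysis":
        flat_labels = flat_labels[atlas.analysis_mask[atlas.brain_mask]]
    sel = flat_labels == roi_label
    if not sel.any():
        raise ValueError(f"ROI label {roi_label} has no voxels in this mask")
    return float(np.asarray(cap_map)[sel].mean())
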