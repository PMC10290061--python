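"""Frame clustering into co-activation patterns (CAPs).

The method treats every fMRI time frame as an m-dimensional spatial vector
(m = voxels in the cerebellum-excluded analysis mask), pools frames across
all subjects, and partitions them with k-means++ under correlation distance
d(u, v) = 1 - Pearson r(u, v). The number of clusters is chosen from the
explained-variance curve EV(K) = V_B / (V_w + V_B): the smallest K beyond
which every additional cluster gains less than 0.5% explained variance.
A CAP is the voxel-wise mean of the z-scored frames in one cluster; combined
and genotype-group CAPs come from the same partition.

Centroid updates use the arithmetic mean of member frames (not re-normalised
vectors), matching the k-means objective D = sum_k sum_{j in k} d^2(z_j, c_k).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import Cap, CapSet, ClusterSolution, FramePool, ImageSeries, VarianceCurve

_ZERO_TOL = 1e-12


class DegenerateVectorWarning(UserWarning):
    """A zero-variance operand was met where correlation is undefined."""


def _row_normalise(x: np.ndarray) -> np.ndarray:
    """Centre rows and scale to unit norm; zero-variance rows become zero.

    After this transform the Pearson correlation of two rows is their dot
    product, and a zero row yields r = 0, i.e. correlation distance 1 — the
    neutral-distance convention for degenerate vectors.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    flat = norms[:, 0] < _ZERO_TOL
    if np.any(flat):
        warnings.warn("zero-variance vector(s); using correlation distance 1",
                      DegenerateVectorWarning, stacklevel=3)
    norms[flat] = 1.0
    out = centred / norms
    out[flat] = 0.0
    return out


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson r(u, v); in [0, 2]. Zero-variance operands give 1."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 3:
        raise ValueError("vectors must have length >= 3")
    un = _row_normalise(u[None, :])[0]
    vn = _row_normalise(v[None, :])[0]
    if not un.any() or not vn.any():
        return 1.0
    return float(1.0 - un @ vn)


def _distances_to_centroids(frames_n: np.ndarray,
                            centroids: np.ndarray) -> np.ndarray:
    """Correlation distances of pre-normalised frames to raw centroids."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateVectorWarning)
        cn = _row_normalise(centroids)
    return 1.0 - frames_n @ cn.T


def concatenate_subjects(series_list: Sequence[ImageSeries],
                         analysis_mask: Optional[np.ndarray] = None
                         ) -> FramePool:
    """Stack subjects' frames (in the given order) into one pool.

    ``analysis_mask`` is a 3-D boolean mask (a subset of the series mask,
    e.g. brain minus cerebellum); columns outside it are dropped. Provenance
    records subject, group and the 0-based within-subject frame index.
    """
    if not series_list:
        raise ValueError("no series to concatenate")
    ref = series_list[0]
    blocks, prov = [], []
    for s in series_list:
        if s.mask.shape != ref.mask.shape or not np.array_equal(s.mask, ref.mask):
            raise ValueError(
                f"mask mismatch: subject {s.subject_id!r} does not share the "
                f"reference mask of {ref.subject_id!r}")
        if s.n_voxels != ref.n_voxels:
            raise ValueError("voxel count mismatch between subjects")
        data = s.data
        if analysis_mask is not None:
            cols = analysis_mask[s.mask]
            data = data[:, cols]
        blocks.append(data)
        prov.append(pd.DataFrame({
            "subject_id": s.subject_id, "group": s.group,
            "frame_index": np.arange(s.n_frames)}))
    mask_id = "analysis" if analysis_mask is not None else ref.mask_id
    return FramePool(np.vstack(blocks), pd.concat(prov, ignore_index=True),
                     mask_id=mask_id)


def _kmeanspp_seed(frames_n: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """D^2-weighted k-means++ seeding under correlation distance.

    Returns indices of k initial centroid frames. The first is uniform; each
    subsequent one is drawn with probability proportional to the squared
    distance to the nearest centroid chosen so far.
    """
    n = frames_n.shape[0]
    centres = [int(rng.integers(n))]
    d2 = (1.0 - frames_n @ frames_n[centres[0]]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all frames coincide with a centre: fall back to uniform
            centres.append(int(rng.integers(n)))
            continue
        probs = d2 / total
        nxt = int(rng.choice(n, p=probs))
        centres.append(nxt)
        d2 = np.minimum(d2, (1.0 - frames_n @ frames_n[nxt]) ** 2)
    return np.asarray(centres)


def _lloyd(frames: np.ndarray, frames_n: np.ndarray, seeds: np.ndarray,
           max_iter: int) -> tuple:
    """Lloyd iterations with mean-of-members centroids.

    Empty clusters are re-seeded at the frame farthest from its current
    centroid. Converges when labels stop changing.
    """
    k = len(seeds)
    centroids = frames[seeds].copy()
    labels = np.full(frames.shape[0], -1)
    converged = False
    for _ in range(max_iter):
        dist = _distances_to_centroids(frames_n, centroids)
        new_labels = dist.argmin(axis=1)
        # re-seed each empty cluster at the frame currently farthest from
        # its centroid, never stealing a frame another empty cluster took
        assigned_d = dist[np.arange(len(new_labels)), new_labels].copy()
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(assigned_d.argmax())
                new_labels[worst] = c
                assigned_d[worst] = -np.inf
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = frames[labels == c].mean(axis=0)
    dist = _distances_to_centroids(frames_n, centroids)
    objective = float((dist[np.arange(len(labels)), labels] ** 2).sum())
    return labels, centroids, objective, converged


def kmeans_corr(pool: FramePool, k: int, seed: int = 0, n_replicates: int = 5,
                max_iter: int = 100) -> ClusterSolution:
    """k-means++ clustering of pooled frames under correlation distance.

    Runs ``n_replicates`` independent seedings and keeps the solution with
    the lowest objective D (sum of squared frame-to-centroid correlation
    distances). Cluster ids are re-ordered by descending size, so CAP 1 is
    always the most frequent pattern; labels are 1-based.
    """
    n = pool.n_frames
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    frames = pool.frames
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateVectorWarning)
        frames_n = _row_normalise(frames)
    master = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        rng = np.random.default_rng(master.integers(2 ** 31))
        seeds = _kmeanspp_seed(frames_n, k, rng)
        labels, centroids, objective, converged = _lloyd(
            frames, frames_n, seeds, max_iter)
        if best is None or objective < best[2]:
            best = (labels, centroids, objective, converged)
    labels, centroids, objective, converged = best
    order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels] + 1
    centroids = centroids[order]
    sizes = np.bincount(labels - 1, minlength=k)
    return ClusterSolution(k=k, labels=labels, centroids=centroids,
                           sizes=sizes, objective=objective, seed=seed,
                           n_replicates=n_replicates, converged=converged)


def explained_variance(pool: FramePool, solution: ClusterSolution) -> tuple:
    """(V_w, V_B, EV) of a clustering under correlation distance.

    V_w = (1/N) sum_k sum_{j in k} d^2(z_j, c_k);
    V_B = (1/N) sum_k n_k d^2(c_k, c) with global centroid
    c = sum_k (n_k/N) c_k; EV = V_B / (V_w + V_B), or 0 when both vanish
    (the K=1 partition).
    """
    if len(solution.labels) != pool.n_frames:
        raise ValueError("solution does not match pool")
    n = pool.n_frames
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateVectorWarning)
        frames_n = _row_normalise(pool.frames)
        dist = _distances_to_centroids(frames_n, solution.centroids)
        v_w = float((dist[np.arange(n), solution.labels - 1] ** 2).sum()) / n
        weights = solution.sizes / n
        global_c = weights @ solution.centroids
        cn = _row_normalise(solution.centroids)
        gn = _row_normalise(global_c[None, :])[0]
        d_cg = 1.0 - cn @ gn
        v_b = float((solution.sizes * d_cg ** 2).sum()) / n
    ev = 0.0 if v_w + v_b == 0 else v_b / (v_w + v_b)
    return v_w, v_b, ev


def build_variance_curve(pool: FramePool, k_min: int = 2, k_max: int = 20,
                         seed: int = 0, n_replicates: int = 5,
                         max_iter: int = 100,
                         gain_threshold: float = 0.005) -> VarianceCurve:
    """EV(K) and its increments over K = k_min..k_max, plus the selected K.

    The fractional gain at K is EV(K) - EV(K-1), i.e. the absolute gain on
    the explained-variance scale; the selection rule takes the smallest K
    after which every gain stays below ``gain_threshold`` (0.005 = 0.5%).
    """
    if k_max > pool.n_frames:
        raise ValueError("k_max cannot exceed the number of frames")
    if k_min < 2 or k_min > k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    ks = np.arange(k_min, k_max + 1)
    v_w = np.empty(len(ks))
    v_b = np.empty(len(ks))
    ev = np.empty(len(ks))
    for i, k in enumerate(ks):
        sol = kmeans_corr(pool, int(k), seed=seed + i,
                          n_replicates=n_replicates, max_iter=max_iter)
        v_w[i], v_b[i], ev[i] = explained_variance(pool, sol)
    gain = np.full(len(ks), np.nan)
    gain[1:] = np.diff(ev)
    curve = VarianceCurve(ks=ks, v_w=v_w, v_b=v_b, explained_variance=ev,
                          fractional_gain=gain)
    curve.selected_k, curve.saturated = _apply_gain_rule(ks, gain,
                                                         gain_threshold)
    return curve


def _apply_gain_rule(ks, gain, threshold):
    # K_max satisfies the rule only vacuously, which is no evidence of
    # saturation: fall back to it with the warning flag instead
    for i, k in enumerate(ks[:-1]):
        later = gain[i + 1:]
        if np.all(later[~np.isnan(later)] < threshold):
            return int(k), True
    return int(ks[-1]), False


def select_optimal_k(curve: VarianceCurve,
                     gain_threshold: float = 0.005) -> int:
    """Smallest K whose every later gain is below the threshold.

    Falls back to the largest K in the curve (with ``curve.saturated`` set
    to False) when the explained variance never saturates.
    """
    k, saturated = _apply_gain_rule(curve.ks, curve.fractional_gain,
                                    gain_threshold)
    curve.selected_k, curve.saturated = k, saturated
    if not saturated:
        warnings.warn("explained variance did not saturate; "
                      "returning the largest K in the curve")
    return k


def build_caps(pool: FramePool, solution: ClusterSolution,
               groups: Sequence[str] = ("WT", "HET")) -> CapSet:
    """Voxel-wise mean maps per cluster: combined plus one map per group.

    The combined map is the occurrence-weighted average of the group maps.
    A cluster with no frames from some group gets ``None`` for that group's
    map (flagged missing rather than fabricated).
    """
    if len(solution.labels) != pool.n_frames:
        raise ValueError("solution does not match pool")
    grp = pool.provenance["group"].to_numpy()
    for g in groups:
        if not np.any(grp == g):
            raise ValueError(f"group {g!r} contributes no frames")
    caps = []
    for cap_id in range(1, solution.k + 1):
        members = solution.labels == cap_id
        combined = pool.frames[members].mean(axis=0) if members.any() else None
        group_maps, counts = {}, {}
        for g in groups:
            sel = members & (grp == g)
            counts[g] = int(sel.sum())
            group_maps[g] = pool.frames[sel].mean(axis=0) if sel.any() else None
        caps.append(Cap(cap_id=cap_id, combined=combined,
                        group_maps=group_maps, member_counts=counts))
    return CapSet(caps=caps, solution=solution, mask_id=pool.mask_id)


def cap_spatial_correlation(cap_a: np.ndarray, cap_b: np.ndarray,
                            mask: Optional[np.ndarray] = None) -> float:
    """Pearson correlation of two CAP maps over a voxel mask."""
    a = np.asarray(cap_a, dtype=float).ravel()
    b = np.asarray(cap_b, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
        if not sel.any():
            raise ValueError("mask selects no voxels")
        a, b = a[sel], b[sel]
    if a.shape != b.shape:
        raise ValueError("maps must share the mask")
    return 1.0 - correlation_distance(a, b)
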