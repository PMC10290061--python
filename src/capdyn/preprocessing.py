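"""Per-subject BOLD preprocessing.

Stages (each individually toggleable, applied in this order by the
pipeline): in-plane Gaussian smoothing, start/end frame trimming, zero-phase
Butterworth band-pass, quadratic detrending, a second trim to absorb filter
edge effects, nuisance regression (global signal and/or supplied motion
regressors), and per-voxel z-scoring. All stages operate voxel-wise on the
``frames x voxels`` matrix except smoothing, which needs the 3-D geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .datatypes import ImageSeries

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def smooth_inplane(series: ImageSeries, fwhm_voxels: float) -> ImageSeries:
    """Gaussian-smooth each frame within 2-D slices only.

    The kernel has sigma = FWHM / 2.3548 in the first two grid axes and zero
    along the slice axis and time, matching in-plane smoothing of axial
    slices. Voxels outside the mask are treated as zero.
    """
    if fwhm_voxels <= 0:
        raise ValueError("fwhm_voxels must be positive")
    sigma = fwhm_voxels / _FWHM_TO_SIGMA
    vol4 = np.zeros(series.mask.shape + (series.n_frames,))
    vol4[series.mask] = series.data.T
    smoothed = ndimage.gaussian_filter(vol4, sigma=(sigma, sigma, 0.0, 0.0),
                                       mode="nearest")
    return series.with_data(smoothed[series.mask].T, note="smooth_inplane")


def trim_frames(series: ImageSeries, n_start: int, n_end: int) -> ImageSeries:
    """Drop the first ``n_start`` and last ``n_end`` frames."""
    if n_start < 0 or n_end < 0:
        raise ValueError("trim counts must be non-negative")
    if series.n_frames <= n_start + n_end:
        raise ValueError(
            f"cannot trim {n_start}+{n_end} frames from a series of "
            f"{series.n_frames}")
    stop = series.n_frames - n_end
    return series.with_data(series.data[n_start:stop], note="trim_frames")


def bandpass_filter(series: ImageSeries, low_hz: float = 0.01,
                    high_hz: float = 0.2, order: int = 5) -> ImageSeries:
    """Zero-phase Butterworth band-pass, applied voxel-wise.

    Uses second-order sections with forward-backward filtering, so the
    effective magnitude response is the squared Butterworth response and the
    phase is zero.
    """
    nyquist = 1.0 / (2.0 * series.tr)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyquist}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / series.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return series.with_data(filtered, note="bandpass_filter")


def quadratic_detrend(series: ImageSeries) -> ImageSeries:
    """Subtract the least-squares quadratic trend from every voxel."""
    n = series.n_frames
    if n < 4:
        raise ValueError("quadratic detrending needs at least 4 frames")
    t = np.arange(n, dtype=float)
    basis = np.vander(t, 3, increasing=True)  # [1, t, t^2]
    coef, *_ = np.linalg.lstsq(basis, series.data, rcond=None)
    return series.with_data(series.data - basis @ coef,
                            note="quadratic_detrend")


def compute_global_signal(series: ImageSeries,
                          brain_columns: Optional[np.ndarray] = None
                          ) -> np.ndarray:
    """Per-frame mean over brain-mask voxels (columns of the data matrix)."""
    if brain_columns is None:
        data = series.data
    else:
        brain_columns = np.asarray(brain_columns)
        if brain_columns.size == 0 or (brain_columns.dtype == bool
                                       and not brain_columns.any()):
            raise ValueError("brain mask selects no voxels")
        data = series.data[:, brain_columns]
    if data.shape[1] == 0:
        raise ValueError("brain mask selects no voxels")
    return data.mean(axis=1)


def regress_nuisance(series: ImageSeries, regressors: np.ndarray,
                     names: Optional[Sequence[str]] = None) -> ImageSeries:
    """OLS-residualise every voxel on the given regressors plus an intercept.

    Raises if the design matrix (including the intercept) is rank deficient,
    naming the redundant columns.
    """
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != series.n_frames:
        reg = reg.T
    if reg.shape[0] != series.n_frames:
        raise ValueError("regressors must have one row per frame")
    names = list(names) if names is not None else [
        f"regressor_{i}" for i in range(reg.shape[1])]
    design = np.column_stack([np.ones(series.n_frames), reg])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        redundant = [names[j - 1] for j in range(1, design.shape[1])
                     if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank]
        raise ValueError(
            f"rank-deficient nuisance design; redundant columns: {redundant}")
    coef, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    return series.with_data(series.data - design @ coef,
                            note="regress_nuisance")


def zscore_voxels(series: ImageSeries, tol: float = 1e-12) -> ImageSeries:
    """Standardise every voxel time series to zero mean, unit variance.

    Constant (zero-variance) voxels are set to zero and flagged on the
    returned series rather than raising.
    """
    if series.n_frames < 2:
        raise ValueError("z-scoring needs at least 2 frames")
    mean = series.data.mean(axis=0)
    sd = series.data.std(axis=0)
    flat = sd < tol
    sd_safe = np.where(flat, 1.0, sd)
    z = (series.data - mean) / sd_safe
    z[:, flat] = 0.0
    out = series.with_data(z, note="zscore_voxels")
    out.zero_variance = flat
    return out


@dataclass
class PreprocessingConfig:
    """Stage toggles and parameters for :func:`preprocess_pipeline`.

    ``trim_pre`` removes scanner-transient frames before filtering;
    ``trim_post`` removes filter edge frames afterwards. Setting
    ``single_trim=True`` collapses the two into the pre-filter trim only
    (the alternative reading of the frame-exclusion rule).
    """

    smooth_fwhm: Optional[float] = 2.0
    trim_pre: tuple = (5, 5)
    trim_post: tuple = (5, 5)
    single_trim: bool = False
    band: Optional[tuple] = (0.01, 0.2)
    butter_order: int = 5
    detrend: bool = True
    global_signal_regression: bool = True
    motion_regressors: Optional[np.ndarray] = None
    zscore: bool = True


def preprocess_pipeline(series: ImageSeries,
                        config: Optional[PreprocessingConfig] = None
                        ) -> ImageSeries:
    """Run the full stage sequence on one subject.

    Order: smooth -> pre-trim -> motion regression -> band-pass -> detrend ->
    post-trim -> global signal regression -> z-score. Each stage records a
    line in ``series.history``.
    """
    cfg = config or PreprocessingConfig()
    out = series
    if cfg.smooth_fwhm:
        out = smooth_inplane(out, cfg.smooth_fwhm)
    if cfg.trim_pre != (0, 0):
        out = trim_frames(out, *cfg.trim_pre)
    if cfg.motion_regressors is not None:
        out = regress_nuisance(out, cfg.motion_regressors)
    if cfg.band is not None:
        out = bandpass_filter(out, *cfg.band, order=cfg.butter_order)
    if cfg.detrend:
        out = quadratic_detrend(out)
    if not cfg.single_trim and cfg.trim_post != (0, 0):
        out = trim_frames(out, *cfg.trim_post)
    if cfg.global_signal_regression:
        gs = compute_global_signal(out)
        scale = np.abs(out.data).max()
        if gs.std() <= 1e-8 * max(scale, 1.0):
            # constant global signal carries no time course to remove;
            # regressing it would be collinear with the intercept
            out = out.with_data(out.data - out.data.mean(axis=0),
                                note="global signal ~constant; mean removal")
        else:
            out = regress_nuisance(out, gs[:, None], names=["global_signal"])
    if cfg.zscore:
        out = zscore_voxels(out)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("preprocessing produced non-finite values")
    return out
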