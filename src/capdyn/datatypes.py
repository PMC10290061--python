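"""Core in-memory containers shared across the pipeline.

All voxel data are stored as 2-D ``frames x voxels`` matrices. The voxel
axis is a deterministic C-order flattening of the 3-D grid restricted to a
boolean mask (``np.argwhere(mask)`` order), so a (series, mask) pair can be
round-tripped through NIfTI losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class ImageSeries:
    """One subject's BOLD series restricted to a mask.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_voxels)
        Real-valued signal, one row per time frame.
    tr : float
        Repetition time in seconds (sampling interval of the frames).
    mask : ndarray of bool, 3-D
        The voxel mask the columns of ``data`` refer to, in C order.
    subject_id, group : str
        Provenance used for pooling and group statistics.
    zero_variance : ndarray of bool, shape (n_voxels,), optional
        Voxels flagged as constant during z-scoring.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    subject_id: str = ""
    group: str = ""
    mask_id: str = "brain"
    zero_variance: Optional[np.ndarray] = None
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x voxels)")
        if self.data.shape[1] != int(np.count_nonzero(self.mask)):
            raise ValueError(
                f"data has {self.data.shape[1]} voxel columns but mask has "
                f"{int(np.count_nonzero(self.mask))} voxels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_index(self) -> np.ndarray:
        """Voxel -> 3-D coordinate map (C order), shape (n_voxels, 3)."""
        return np.argwhere(self.mask)

    def with_data(self, data: np.ndarray, note: str | None = None) -> "ImageSeries":
        """Return a copy holding ``data``; appends ``note`` to the history."""
        out = replace(self, data=np.asarray(data, dtype=float),
                      history=list(self.history))
        if note:
            out.history.append(f"{note}: {self.data.shape[0]} -> {data.shape[0]} frames")
        return out


@dataclass
class FramePool:
    """Concatenated frames across subjects with per-frame provenance.

    ``frames`` is the N x m matrix of masked voxel vectors; ``provenance``
    has one row per pooled frame with columns ``subject_id``, ``group`` and
    ``frame_index`` (0-based index within the source subject).
    """

    frames: np.ndarray
    provenance: pd.DataFrame
    mask_id: str = "analysis"

    def __post_init__(self) -> None:
        if len(self.provenance) != self.frames.shape[0]:
            raise ValueError("provenance must have one row per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.frames.shape[1]

    def subset(self, keep: np.ndarray) -> "FramePool":
        keep = np.asarray(keep)
        return FramePool(self.frames[keep],
                         self.provenance.iloc[keep].reset_index(drop=True),
                         self.mask_id)


@dataclass
class ClusterSolution:
    """Result of frame clustering under correlation distance.

    ``labels`` are 1-based CAP ids (1..k). ``objective`` is the sum of
    squared correlation distances of every frame to its centroid.
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    objective: float
    seed: Optional[int] = None
    n_replicates: int = 1
    converged: bool = True

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("cluster sizes must sum to the number of frames")


@dataclass
class VarianceCurve:
    """Explained-variance curve over a range of cluster counts."""

    ks: np.ndarray
    v_w: np.ndarray
    v_b: np.ndarray
    explained_variance: np.ndarray
    fractional_gain: np.ndarray  # gain[i] = EV(k_i) - EV(k_i - 1); NaN for the first k
    selected_k: Optional[int] = None
    saturated: bool = True  # False when no k satisfies the gain rule

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.ks, "v_w": self.v_w, "v_b": self.v_b,
            "explained_variance": self.explained_variance,
            "fractional_gain": self.fractional_gain,
        })


@dataclass
class Cap:
    """A single co-activation pattern: combined and per-group mean maps."""

    cap_id: int
    combined: np.ndarray
    group_maps: dict
    member_counts: dict
    significance: dict = field(default_factory=dict)


@dataclass
class CapSet:
    caps: list
    solution: Optional[ClusterSolution] = None
    mask_id: str = "analysis"

    @property
    def k(self) -> int:
        return len(self.caps)

    def __iter__(self):
        return iter(self.caps)

    def __getitem__(self, cap_id: int) -> Cap:
        for cap in self.caps:
            if cap.cap_id == cap_id:
                return cap
        raise KeyError(f"no CAP with id {cap_id}")
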