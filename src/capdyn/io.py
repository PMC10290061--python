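"""NIfTI / CSV / YAML input-output.

Conventions: voxel columns of a 2-D series matrix follow the C-order
flattening of the 3-D grid restricted to the mask (``np.argwhere(mask)``
order); frame indices and voxel coordinates are 0-based; CAP ids are
1-based. The TR is stored in (and read back from) the 4th pixdim of the
NIfTI header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import ImageSeries
from .synthetic import SyntheticAtlas, SyntheticCohort

_EYE4 = np.eye(4)


def write_mask(mask: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _EYE4)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_series(series: ImageSeries, path) -> None:
    """Write one subject as a 4-D NIfTI (zeros outside the mask)."""
    vol4 = np.zeros(series.mask.shape + (series.n_frames,), dtype=np.float32)
    vol4[series.mask] = series.data.T
    img = nib.Nifti1Image(vol4, _EYE4)
    img.header.set_zooms((1.0, 1.0, 1.0, float(series.tr)))
    nib.save(img, str(path))


def read_series(path, mask: np.ndarray, subject_id: str = "",
                group: str = "", tr: Optional[float] = None) -> ImageSeries:
    img = nib.load(str(path))
    vol4 = np.asarray(img.dataobj, dtype=float)
    if vol4.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series")
    if vol4.shape[:3] != mask.shape:
        raise ValueError(
            f"{path}: grid {vol4.shape[:3]} does not match mask {mask.shape}")
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return ImageSeries(data=vol4[mask].T, tr=tr, mask=mask,
                       subject_id=subject_id, group=group)


def write_map(map_vector: np.ndarray, mask: np.ndarray, path) -> None:
    """Write a per-voxel map (over mask columns) as a 3-D NIfTI."""
    vol = np.zeros(mask.shape, dtype=np.float32)
    vol[mask] = np.asarray(map_vector, dtype=np.float32)
    nib.save(nib.Nifti1Image(vol, _EYE4), str(path))


def read_map(path, mask: np.ndarray) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.shape != mask.shape:
        raise ValueError(f"{path}: grid mismatch with mask")
    return vol[mask]


def write_atlas(atlas: SyntheticAtlas, path, names_path=None) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), _EYE4), str(path))
    if names_path is not None:
        pd.DataFrame({
            "label": list(atlas.roi_names),
            "name": list(atlas.roi_names.values()),
            "excluded": [lab == atlas.excluded_label
                         for lab in atlas.roi_names],
        }).to_csv(names_path, index=False)


def read_atlas(path, names_path) -> SyntheticAtlas:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    names = pd.read_csv(names_path)
    roi_names = dict(zip(names["label"].astype(int), names["name"]))
    excluded = names.loc[names["excluded"], "label"]
    excluded_label = int(excluded.iloc[0]) if len(excluded) else -1
    brain = labels > 0
    analysis = brain & (labels != excluded_label)
    return SyntheticAtlas(tuple(labels.shape), labels, roi_names, brain,
                          analysis, excluded_label)


def read_subject_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(table.columns)
    if missing:
        raise ValueError(f"subject table lacks columns {sorted(missing)}")
    dupes = table["subject_id"][table["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate subject IDs: {sorted(set(dupes))}")
    return table


def read_regressors(path) -> np.ndarray:
    """Nuisance regressors (e.g. motion vectors) as whitespace-delimited
    text, one row per frame."""
    reg = np.loadtxt(str(path), ndmin=2)
    return reg


def exclude_subjects(table: pd.DataFrame, exclude_ids) -> pd.DataFrame:
    """Drop excluded subjects (e.g. mis-genotyped animals) from the table."""
    exclude_ids = set(exclude_ids)
    unknown = exclude_ids - set(table["subject_id"])
    if unknown:
        raise ValueError(f"cannot exclude unknown subjects: {sorted(unknown)}")
    return table[~table["subject_id"].isin(exclude_ids)].reset_index(drop=True)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write a synthetic cohort to disk; returns a path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"atlas": str(outdir / "atlas.nii"),
             "roi_names": str(outdir / "roi_names.csv"),
             "brain_mask": str(outdir / "brain_mask.nii"),
             "analysis_mask": str(outdir / "analysis_mask.nii"),
             "subject_table": str(outdir / "subjects.csv"),
             "state_sequences": str(outdir / "state_sequences.csv"),
             "config": str(outdir / "ground_truth.yaml"),
             "series": {}}
    write_atlas(cohort.atlas, paths["atlas"], paths["roi_names"])
    write_mask(cohort.atlas.brain_mask, paths["brain_mask"])
    write_mask(cohort.atlas.analysis_mask, paths["analysis_mask"])
    cohort.subject_table.to_csv(paths["subject_table"], index=False)
    seq = pd.DataFrame(cohort.state_sequences)
    seq.insert(0, "frame_index", np.arange(len(seq)))
    seq.to_csv(paths["state_sequences"], index=False)
    model = cohort.model
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({
            "k_true": int(model.k_true), "n_frames": int(model.n_frames),
            "tr_seconds": float(model.tr),
            "group_sizes": [int(n) for n in model.group_sizes],
            "groups": list(model.groups),
            "dwell_mean_frames": model.dwell_mean_frames.tolist(),
            "occurrence_bias": model.occurrence_bias.tolist(),
            "noise_sd": float(model.noise_sd), "ar1": float(model.ar1),
            "seed": int(cohort.seed),
        }, fh)
    for s in cohort.subjects:
        p = str(outdir / f"{s.subject_id}.nii")
        write_series(s, p)
        paths["series"][s.subject_id] = p
    return paths


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
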