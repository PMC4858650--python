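"""File I/O: NIfTI volumes, cohort / acquisition / index CSV tables, YAML.

CSV schemas
-----------
cohort.csv
    One row per animal: identity, group, Ishak score, covariates, liver
    volume, injected dose and the kinetic parameters (see
    ``cohort.cohort_to_frame``).
acquisitions.csv
    Long format, one row per (animal, scan, frame, organ):
    ``animal_id, scan, frame_index, t_start_s, t_end_s, organ, counts,
    injected_MBq, calibration``.  ``scan`` is ``dynamic`` or ``static``.
indices.csv
    One row per animal: ``animal_id, group, ishak, luv, hh15, lhl15,
    liver_volume_mL``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .acquisition import DynamicAcquisition
from .phantom import LABEL_LEGEND, ORGAN_LABELS, LabelVolume

__all__ = [
    "save_label_volume",
    "load_label_volume",
    "save_counts_nifti",
    "acquisitions_to_frame",
    "acquisitions_from_frame",
    "load_yaml",
    "dump_yaml",
]


def _affine(voxel_size_mm):
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_label_volume(phantom: LabelVolume, path) -> None:
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), _affine(phantom.voxel_size_mm))
    nib.save(img, str(path))


def load_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=np.asarray(img.dataobj).astype(np.int16),
                       voxel_size_mm=voxel, legend=dict(LABEL_LEGEND))


def save_counts_nifti(acq: DynamicAcquisition, voxel_size_mm, path) -> None:
    """Write a voxel-mode acquisition as a 4-D NIfTI (frames last)."""
    if acq.mode != "voxel":
        raise ValueError("only voxel-mode acquisitions can be written as NIfTI")
    data = np.moveaxis(np.asarray(acq.counts), 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float64), _affine(voxel_size_mm)), str(path))


def acquisitions_to_frame(records) -> pd.DataFrame:
    """Flatten ROI-mode acquisitions into the long acquisitions table.

    ``records`` is an iterable of ``(animal_id, scan_name, acquisition)``.
    """
    rows = []
    for animal_id, scan, acq in records:
        if acq.mode != "roi":
            raise ValueError("only ROI-mode acquisitions go in the CSV table")
        for i, (t0, t1) in enumerate(acq.frames):
            for j, organ in enumerate(acq.organ_labels):
                rows.append({
                    "animal_id": animal_id,
                    "scan": scan,
                    "frame_index": i,
                    "t_start_s": t0,
                    "t_end_s": t1,
                    "organ": organ,
                    "counts": acq.counts[i, j],
                    "injected_MBq": acq.injected_MBq,
                    "calibration": acq.calibration,
                })
    return pd.DataFrame(rows)


def acquisitions_from_frame(df: pd.DataFrame) -> dict:
    """Rebuild ``{(animal_id, scan): DynamicAcquisition}`` from the table."""
    out = {}
    for (animal_id, scan), sub in df.groupby(["animal_id", "scan"], sort=False):
        sub = sub.sort_values(["frame_index", "organ"])
        frames = (
            sub.drop_duplicates("frame_index")[["t_start_s", "t_end_s"]]
            .to_numpy(dtype=float)
        )
        n_frames = frames.shape[0]
        counts = np.zeros((n_frames, len(ORGAN_LABELS)))
        for j, organ in enumerate(ORGAN_LABELS):
            counts[:, j] = (
                sub[sub["organ"] == organ].sort_values("frame_index")["counts"].to_numpy()
            )
        out[(animal_id, scan)] = DynamicAcquisition(
            frames=frames,
            counts=counts,
            injected_MBq=float(sub["injected_MBq"].iloc[0]),
            calibration=float(sub["calibration"].iloc[0]),
            mode="roi",
        )
    return out


def load_yaml(path) -> dict:
    with open(path, "r") as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
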