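"""File I/O: NIfTI volumes and masks, CSV feature tables, JSON ground truth.

Volumes are written as NIfTI-1 with the voxel spacing in the affine; a 4-D
file holds all four timepoints (one file per timepoint is also accepted on
read).  Feature tables are RFC-4180 CSV with a header row, a ``case_id``
column and a ``label`` column; numeric values round-trip losslessly at 17
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import RadbpeError
from .tables import FeatureTable, infer_block
from .volume import DceVolume, DEFAULT_TIMES


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(volume: DceVolume, path) -> None:
    """Write the 4-D volume as one NIfTI-1 file; acquisition times go in the
    header description."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing))
    img.header["descrip"] = ("times=" + ",".join(f"{t:g}" for t in volume.times)).encode()
    nib.save(img, str(path))


def read_volume(path, times=None) -> DceVolume:
    """Read a DCE volume from one 4-D NIfTI file or a list of four 3-D files."""
    if isinstance(path, (list, tuple)):
        imgs = [nib.load(str(p)) for p in path]
        data = np.stack([np.asarray(i.dataobj, dtype=np.float64) for i in imgs], axis=-1)
        header = imgs[0]
    else:
        header = nib.load(str(path))
        data = np.asarray(header.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise RadbpeError(f"expected 4-D NIfTI, got shape {data.shape}")
    spacing = tuple(float(z) for z in header.header.get_zooms()[:3])
    if times is None:
        desc = header.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
        if desc.startswith("times="):
            times = tuple(float(t) for t in desc[len("times="):].split(","))
        else:
            times = DEFAULT_TIMES
    return DceVolume(data, spacing=spacing, times=tuple(times))


def write_mask(mask: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_map(map_data: np.ndarray, valid: np.ndarray, spacing, path) -> None:
    """Write a float32 parametric map with a paired ``*_valid`` mask file."""
    path = Path(path)
    data = np.where(valid, map_data, 0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(spacing)), str(path))
    valid_path = path.with_name(path.name.replace(".nii", "_valid.nii"))
    write_mask(valid, spacing, valid_path)


def write_ground_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float))


def write_feature_csv(table: FeatureTable, path, label_column: str = "label") -> None:
    frame = table.to_frame(label_column)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path, label_column: str = "label",
                     id_column: str = "case_id") -> FeatureTable:
    """Read a feature table; block tags are inferred from the study-export-style column
    names (``parenchyma *`` → BPE texture, ``tumor *`` → tumor texture,
    ``breast density`` → density, anything else → clinical)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if label_column not in frame.columns:
        raise RadbpeError(f"{path}: missing label column {label_column!r}")
    if id_column in frame.columns and frame[id_column].duplicated().any():
        raise RadbpeError(f"{path}: duplicate case ids")
    feature_cols = [c for c in frame.columns if c not in (label_column, id_column)]
    blocks = {c: infer_block(c) for c in feature_cols}
    return FeatureTable.from_frame(frame, label_column, id_column, blocks)
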