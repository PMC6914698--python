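"""NIfTI and gradient-table input/output.

All volumes live on a cohort-common grid with an identity-rotation affine whose
diagonal carries the voxel size in mm. Gradient tables follow the common
two-file plain-text convention: a ``bvals`` file with one whitespace-delimited
row of b-values (s/mm^2) and a ``bvecs`` file with three rows (x, y, z
components), one column per DWI volume; b=0 columns carry the zero vector.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_volume",
    "load_volume",
    "load_mask",
    "write_gradient_table",
    "read_gradient_table",
    "write_manifest",
    "read_manifest",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(path: str | os.PathLike, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0),
                dtype=None, description: str = "") -> Path:
    """Write a 3D/4D array as NIfTI-1 with a diagonal affine."""
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, _affine(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm) + (1.0,) * (arr.ndim - 3))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return path


def load_volume(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, voxel size in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a NIfTI binary mask as a boolean array; values must be {0,1}."""
    data, _ = load_volume(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask {path} contains non-binary values {vals[:10]}")
    return data.astype(bool)


def write_gradient_table(bvals_path, bvecs_path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """Write the one-row bvals file and three-row bvecs file."""
    bvals = np.atleast_1d(np.asarray(bvals, dtype=float))
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(f"bvecs shape {bvecs.shape} does not match {len(bvals)} b-values")
    np.savetxt(bvals_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, bvecs.T, fmt="%.8f")


def read_gradient_table(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray]:
    """Read (bvals, bvecs) with bvecs returned as (n_volumes, 3)."""
    bvals = np.loadtxt(bvals_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # ambiguous but row-per-axis is the written convention
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(
            f"gradient table mismatch: {len(bvals)} b-values vs bvecs shape {bvecs.shape}"
        )
    return bvals, bvecs


MANIFEST_COLUMNS = ["subject_id", "cohort", "modality", "path", "seed"]


def write_manifest(path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})
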