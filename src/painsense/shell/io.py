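"""Volumetric and tabular I/O.

Voxel ordering convention: masked vectors list voxels in Fortran order,
i.e. the first image axis varies fastest.  All voxel indices are 0-based;
world coordinates are reached only through the affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "vectorize",
    "unvectorize",
    "read_volume",
    "write_volume",
    "read_map_stack",
    "write_stat_map",
    "read_behavior_table",
    "write_behavior_table",
]

AFFINE_ATOL = 1e-4


def vectorize(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract masked voxels as a vector (first axis fastest-varying)."""
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    return volume.ravel(order="F")[mask.ravel(order="F")]


def unvectorize(vector: np.ndarray, mask: np.ndarray,
                fill: float = 0.0) -> np.ndarray:
    """Place a masked vector back into a full volume."""
    if vector.shape[0] != int(mask.sum()):
        raise ValueError("vector length does not match mask voxel count")
    flat = np.full(mask.size, fill, dtype=float)
    flat[mask.ravel(order="F")] = vector
    return flat.reshape(mask.shape, order="F")


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def write_volume(volume: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(volume, affine), str(path))
    return path


def read_map_stack(paths, mask: np.ndarray | None = None,
                   mask_affine: np.ndarray | None = None):
    """Load participant images into a (n, n_voxels) matrix.

    ``paths`` is a sequence of 3-D image paths or a single 4-D image path.
    All affines must agree within ``AFFINE_ATOL``.  Without an explicit
    mask, voxels that are finite and nonzero in at least one image are kept.

    Returns ``(matrix, mask, affine)``.
    """
    if isinstance(paths, (str, Path)):
        data, affine = read_volume(paths)
        if data.ndim != 4:
            raise ValueError("single path must point to a 4-D image")
        vols = [data[..., i] for i in range(data.shape[-1])]
    else:
        vols, affine = [], None
        for p in paths:
            data, aff = read_volume(p)
            if affine is None:
                affine = aff
            elif not np.allclose(aff, affine, atol=AFFINE_ATOL):
                raise ValueError(f"affine mismatch in {p}")
            vols.append(data)
    if mask is None:
        stack = np.stack(vols)
        mask = np.any(np.isfinite(stack) & (stack != 0), axis=0)
    elif mask_affine is not None and not np.allclose(
            mask_affine, affine, atol=AFFINE_ATOL):
        raise ValueError("mask affine does not match image affines")
    matrix = np.stack([vectorize(v, mask) for v in vols])
    return matrix, mask, affine


def write_stat_map(vector: np.ndarray, mask: np.ndarray,
                   affine: np.ndarray, path) -> Path:
    """Write a masked statistic vector as a float32 NIfTI volume."""
    vol = unvectorize(np.asarray(vector, dtype=float), mask, fill=np.nan)
    return write_volume(vol.astype(np.float32), affine, path)


def read_behavior_table(path) -> pd.DataFrame:
    """Trial-level behavior CSV; missing values spelled "NA"."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    required = {"participant_id", "condition", "trial_index", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    keys = df[["participant_id", "condition", "trial_index"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (participant, condition, trial) keys")
    return df


def write_behavior_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="NA")
    return path
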