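"""NIfTI-1 input/output for volumes, masks and sample manifests.

Probability volumes are stored as 32-bit float, masks as unsigned 8-bit.
A subject's stochastic sample stack on disk is either a set of per-sample
files listed in a manifest CSV (columns ``subject_id, member, realization,
path``) or a single 4-D NIfTI whose fourth axis runs member-major,
realization-minor.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BinaryMask, ImageGrid, ScalarVolume

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "read_manifest",
    "write_manifest",
]

#: values this close to 0 or 1 are coerced when reading a mask
MASK_TOLERANCE = 1e-3

MANIFEST_COLUMNS = ("subject_id", "member", "realization", "path")


def _grid_from_image(img: nib.Nifti1Image) -> ImageGrid:
    shape = img.shape[:3]
    return ImageGrid(shape=tuple(int(s) for s in shape), affine=np.asarray(img.affine, float))


def read_volume(path: str | os.PathLike, expect_probability: bool = False) -> ScalarVolume:
    """Read a 3-D NIfTI volume.

    With ``expect_probability`` the value range is validated against [0, 1]
    and the returned volume is flagged as a probability map.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"cannot read volume {path!r}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    grid = _grid_from_image(img)
    return ScalarVolume(grid=grid, values=data, is_probability=expect_probability)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask, coercing values within ``MASK_TOLERANCE`` of {0, 1}."""
    vol = read_volume(path, expect_probability=False)
    data = vol.values
    near0 = np.abs(data) <= MASK_TOLERANCE
    near1 = np.abs(data - 1.0) <= MASK_TOLERANCE
    bad = ~(near0 | near1)
    if bad.any():
        offenders = data[bad]
        raise ValueError(
            f"{path!r}: {bad.sum()} voxel(s) are not within {MASK_TOLERANCE} of 0 or 1 "
            f"(e.g. {offenders.flat[0]:.6g})"
        )
    return BinaryMask(grid=vol.grid, values=near1.astype(np.uint8))


def write_volume(volume: ScalarVolume, path: str | os.PathLike) -> None:
    """Write a volume as float32 NIfTI; round-trips values to within 1e-6."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.grid.affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write volume to {path!r}: {exc}") from exc


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write mask to {path!r}: {exc}") from exc


def write_manifest(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a sample manifest CSV (subject_id, member, realization, path)."""
    missing = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    rows.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path!r} is missing columns: {sorted(missing)}")
    return df
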