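"""Reading and writing volumes.

NIfTI (via nibabel) is the primary on-disk format: scalar volumes as float32,
masks as 0/1 uint8.  Only axis-aligned affines (diagonal direction matrix with
positive spacings) are accepted, matching the package's grid model.

DICOM import (via pydicom) covers RT Dose (with dose-grid scaling) and
RTSTRUCT contours rasterized to voxel-center masks; see :mod:`dicom_io`.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .grids import BinaryMask, ScalarVolume, VolumeGrid

__all__ = ["grid_from_affine", "affine_from_grid", "load_volume", "load_mask",
           "save_volume", "save_mask"]


def affine_from_grid(grid: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def grid_from_affine(affine: np.ndarray, shape) -> VolumeGrid:
    rot = np.asarray(affine, dtype=float)[:3, :3]
    if not np.allclose(rot, np.diag(np.diagonal(rot)), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.diagonal(rot)
    if np.any(spacing <= 0):
        raise ValueError("affine must have positive diagonal spacings")
    return VolumeGrid(
        origin=tuple(np.asarray(affine)[:3, 3]),
        spacing=tuple(spacing),
        size=tuple(int(s) for s in shape[:3]),
    )


def load_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    grid = grid_from_affine(img.affine, img.shape)
    return ScalarVolume(grid, np.asarray(img.dataobj, dtype=np.float32))


def load_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    grid = grid_from_affine(img.affine, img.shape)
    return BinaryMask(grid, np.asarray(img.dataobj) > 0.5)


def save_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine_from_grid(volume.grid))
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine_from_grid(mask.grid))
    nib.save(img, str(path))
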