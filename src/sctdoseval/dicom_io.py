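"""Optional DICOM-RT import: RT Dose grids and RTSTRUCT contour masks.

RT Dose volumes are converted with their DoseGridScaling and
GridFrameOffsetVector; RTSTRUCT contours are rasterized per axial slice by
voxel-center point-in-polygon tests onto a caller-supplied grid.  Export back
to DICOM is out of scope.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as _MplPath

from .grids import BinaryMask, ScalarVolume, VolumeGrid

__all__ = ["rtdose_to_volume", "rtstruct_to_mask"]


def rtdose_to_volume(ds) -> ScalarVolume:
    """Convert a pydicom RT Dose dataset to a :class:`ScalarVolume` (Gy).

    Pixel data are scaled by DoseGridScaling.  The DICOM frame axis maps to
    the grid's z axis; rows/columns map to y/x, so the returned array is
    indexed (x, y, z) like every other volume in the package.
    """
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    frames = ds.pixel_array.astype(np.float64) * scaling  # (frame, row, col)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    z_sp = float(dz[0]) if len(dz) else 1.0
    if z_sp <= 0:
        raise ValueError("GridFrameOffsetVector must be increasing")
    grid = VolumeGrid(
        origin=(ipp[0], ipp[1], ipp[2] + offsets[0]),
        spacing=(col_sp, row_sp, z_sp),
        size=(frames.shape[2], frames.shape[1], frames.shape[0]),
    )
    values = np.transpose(frames, (2, 1, 0))  # (col=x, row=y, frame=z)
    return ScalarVolume(grid, values)


def rtstruct_to_mask(ds, roi_name: str, grid: VolumeGrid) -> BinaryMask:
    """Rasterize one RTSTRUCT ROI onto ``grid`` (axial point-in-polygon).

    Each ContourSequence item is a closed planar polygon at constant z; a
    voxel center is inside the mask if it lies inside an odd number of
    polygons on its nearest slice.
    """
    number = None
    for roi in ds.StructureSetROISequence:
        if str(roi.ROIName) == roi_name:
            number = roi.ROINumber
            break
    if number is None:
        raise KeyError(f"ROI {roi_name!r} not found in RTSTRUCT")

    contour_set = None
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber == number:
            contour_set = getattr(rc, "ContourSequence", [])
            break
    if contour_set is None:
        raise KeyError(f"ROI {roi_name!r} has no contour data")

    out = np.zeros(grid.size, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])

    for contour in contour_set:
        data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
        z = float(np.mean(data[:, 2]))
        k = int(np.argmin(np.abs(zs - z)))
        if abs(zs[k] - z) > grid.spacing[2]:
            continue  # contour plane outside the grid
        inside = _MplPath(data[:, :2]).contains_points(pts).reshape(len(xs), len(ys))
        out[:, :, k] ^= inside  # XOR supports holes (nested contours)
    return BinaryMask(grid, out)
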