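"""Voxel-geometry data model: grids, scalar volumes, binary masks.

Conventions
-----------
* 0-based indices; the physical coordinate of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (voxel-*center* convention).
* Axes are axis-aligned with the patient-based coordinate system; oblique
  grids are out of scope.
* Masks live on voxel centers with no partial-volume weighting, so every
  derived volume/ratio is an exact voxel count times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "GridMismatchError",
    "EmptyStructureError",
    "resample",
    "threshold_mask",
    "mask_volume",
]

#: Fill values used when a resampling target voxel falls outside the source
#: extent.  Fixed (not guessed from data) so boundary behavior is deterministic.
IMAGE_FILL_HU = -1000.0
DOSE_FILL_GY = 0.0


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


class EmptyStructureError(ValueError):
    """A structure mask required to be non-empty has no voxels."""


@dataclass(frozen=True)
class VolumeGrid:
    """Regular, axis-aligned 3D voxel lattice.

    Parameters
    ----------
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    spacing : tuple of float
        Voxel pitch (mm) along each axis; strictly positive.
    size : tuple of int
        Number of voxels along each axis; at least 1.
    orientation : str
        Axis-direction convention tag (informational; all grids in one
        analysis must share it).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    size: tuple[int, int, int]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.size) != 3:
            raise ValueError("origin, spacing and size must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise ValueError(f"sizes must be >= 1, got {self.size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.size

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.size[axis])

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """(min, max) voxel-center coordinate per axis."""
        return tuple(
            (self.origin[a], self.origin[a] + self.spacing[a] * (self.size[a] - 1))
            for a in range(3)
        )

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + ijk * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates of physical points."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
        )

    def overlaps(self, other: "VolumeGrid") -> bool:
        for (lo_a, hi_a), (lo_b, hi_b) in zip(self.extent, other.extent):
            if max(lo_a, lo_b) > min(hi_a, hi_b):
                return False
        return True

    def meshgrid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (1D-per-axis) world-coordinate arrays for rendering."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z


def _check_shape(grid: VolumeGrid, values: np.ndarray) -> None:
    if tuple(values.shape) != grid.size:
        raise ValueError(
            f"value array shape {values.shape} does not match grid size {grid.size}"
        )


@dataclass
class ScalarVolume:
    """A scalar field (HU or Gy) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _check_shape(self.grid, self.values)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    """A boolean structure mask on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        _check_shape(self.grid, self.values)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.values.copy())


def _require_same_grid(a, b, what: str) -> None:
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError(
            f"{what}: grids differ (size {a.grid.size} vs {b.grid.size}, "
            f"origin {a.grid.origin} vs {b.grid.origin}, "
            f"spacing {a.grid.spacing} vs {b.grid.spacing})"
        )


def resample(
    volume,
    target: VolumeGrid,
    mode: str = "trilinear",
    fill_value: float | None = None,
):
    """Resample a volume or mask onto ``target`` by interpolating at its
    voxel centers.

    ``mode`` is ``"trilinear"`` (images/dose) or ``"nearest"`` (masks; a
    :class:`BinaryMask` input always uses nearest).  Target voxels outside
    the source extent get ``fill_value`` (default −1000 HU for images, False
    for masks; pass 0.0 for dose).
    """
    is_mask = isinstance(volume, BinaryMask)
    src_grid = volume.grid
    if not src_grid.overlaps(target):
        raise GridMismatchError(
            f"source and target grids do not overlap: source extent "
            f"{src_grid.extent}, target extent {target.extent}"
        )
    if src_grid.same_geometry(target):
        out = volume.copy()
        out.grid = target
        return out

    if is_mask:
        mode = "nearest"
        fill = 0.0
    elif fill_value is None:
        fill = IMAGE_FILL_HU
    else:
        fill = float(fill_value)

    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    order = 0 if mode == "nearest" else 1
    from . import _kernels

    src_vals = np.ascontiguousarray(volume.values, dtype=np.float32)
    out_vals = _kernels.resample_axes(
        src_vals,
        *src_grid.origin,
        *src_grid.spacing,
        target.axis_coords(0),
        target.axis_coords(1),
        target.axis_coords(2),
        order,
        np.float32(fill),
    )
    if is_mask:
        return BinaryMask(target, out_vals > 0.5)
    return ScalarVolume(target, out_vals)


def threshold_mask(
    image: ScalarVolume, threshold: float, within: BinaryMask | None = None
) -> BinaryMask:
    """Voxels with ``image >= threshold`` (HU), optionally restricted to a
    region mask sharing the image grid."""
    member = image.values >= threshold
    if within is not None:
        _require_same_grid(image, within, "threshold_mask")
        member &= within.values
    return BinaryMask(image.grid, member)


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in cm³ (true-voxel count × voxel volume)."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3 / 1000.0
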