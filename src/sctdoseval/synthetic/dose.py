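"""Simplified two-mode ray-trace dose model.

This is deliberately *not* a transport engine.  It provides exactly the two
properties the evaluation pipeline needs from a dose calculation:

1. sensitivity of the dose to the image's HU values along each beam path
   (via an HU → relative-electron-density calibration curve and exponential
   attenuation of radiological depth), and
2. a ``water`` / ``medium`` reporting mode: in medium mode the local
   deposition is multiplied by a density-dependent factor (up to 1.11 at a
   relative electron density of 1.6, echoing the reported dose-to-medium vs
   dose-to-water gap of up to ~11% in cortical bone), so bone — real or
   mislabeled — receives systematically different dose than in water mode.

Beams are parallel axial fields at configurable gantry angles whose
aperture is the PTV projection plus a margin; primary dose falls off as
exp(−μ_eff × radiological depth) and is smoothed laterally by a Gaussian
scatter kernel.  The summed dose is scaled so the PTV mean equals the
prescription exactly.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..grids import BinaryMask, ScalarVolume, VolumeGrid, resample

__all__ = ["DoseModelSpec", "compute_dose", "dose_grid_for", "hu_to_red"]


@dataclass(frozen=True)
class DoseModelSpec:
    """Parameters of the simplified dose model."""

    gantry_angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    mu_per_mm: float = 0.005              # effective attenuation per unit rad. depth
    scatter_sigma_mm: float = 3.0
    mode: str = "water"                   # or "medium"
    #: HU -> relative electron density anchors (linear between, clamped outside)
    calibration: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.001),
        (0.0, 1.0),
        (1000.0, 1.6),
    )
    #: medium-mode deposition factor vs relative electron density
    medium_factor: tuple[tuple[float, float], ...] = ((1.05, 1.0), (1.6, 1.11))
    dose_grid_spacing_mm: float = 2.5
    beam_margin_mm: float = 5.0

    def validate(self) -> None:
        if len(self.gantry_angles_deg) < 1:
            raise ValueError("need at least one beam")
        if self.mode not in ("water", "medium"):
            raise ValueError(f"unknown dose mode {self.mode!r}")
        hu = [a[0] for a in self.calibration]
        red = [a[1] for a in self.calibration]
        if sorted(hu) != list(hu) or sorted(red) != list(red):
            raise ValueError("calibration curve must be monotone non-decreasing")
        if self.mu_per_mm <= 0 or self.dose_grid_spacing_mm <= 0:
            raise ValueError("mu and dose grid spacing must be positive")


def hu_to_red(hu: np.ndarray, spec: DoseModelSpec) -> np.ndarray:
    """Relative electron density from HU via the piecewise-linear curve."""
    anchors_hu = np.asarray([a[0] for a in spec.calibration])
    anchors_red = np.asarray([a[1] for a in spec.calibration])
    return np.interp(hu, anchors_hu, anchors_red)


def dose_grid_for(image_grid: VolumeGrid, spacing_mm: float) -> VolumeGrid:
    """Isotropic dose grid covering the image extent."""
    ext = image_grid.extent
    size = tuple(
        int(np.floor((hi - lo) / spacing_mm)) + 1 for lo, hi in ext
    )
    return VolumeGrid(
        origin=tuple(lo for lo, _ in ext),
        spacing=(spacing_mm, spacing_mm, spacing_mm),
        size=size,
    )


def _rotate(vol: np.ndarray, angle_deg: float, order: int, cval: float) -> np.ndarray:
    """In-plane (x–y) rotation; exact array ops for multiples of 180°."""
    angle = angle_deg % 360.0
    if angle == 0.0:
        return vol
    if angle == 180.0:
        return vol[::-1, ::-1, :]
    return ndimage.rotate(
        vol, angle, axes=(0, 1), reshape=False, order=order,
        mode="constant", cval=cval, prefilter=False,
    )


def compute_dose(
    image: ScalarVolume,
    ptv: BinaryMask,
    spec: DoseModelSpec | None = None,
    prescription_gy: float = 50.0,
    dose_grid: VolumeGrid | None = None,
) -> ScalarVolume:
    """Deterministic dose distribution of a PTV-directed multi-beam plan."""
    spec = spec or DoseModelSpec()
    spec.validate()
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    grid = dose_grid or dose_grid_for(image.grid, spec.dose_grid_spacing_mm)

    red_img = ScalarVolume(image.grid, hu_to_red(image.values, spec))
    red = resample(red_img, grid, mode="trilinear", fill_value=0.001).values.astype(
        np.float64
    )
    ptv_d = resample(ptv, grid, mode="nearest")
    if ptv_d.voxel_count == 0:
        raise ValueError("PTV outside beam coverage: no PTV voxels on the dose grid")

    sp = grid.spacing[0]  # isotropic by construction
    margin_vox = max(int(round(spec.beam_margin_mm / sp)), 0)
    sigma_vox = spec.scatter_sigma_mm / sp

    total = np.zeros(grid.size, dtype=np.float64)
    for angle in spec.gantry_angles_deg:
        red_rot = _rotate(red, angle, order=1, cval=0.001)
        ptv_rot = _rotate(ptv_d.values.astype(np.float32), angle, order=0, cval=0.0) > 0.5
        # radiological depth at voxel centers along the beam axis (axis 0)
        depth = (np.cumsum(red_rot, axis=0) - 0.5 * red_rot) * sp
        beam = np.exp(-spec.mu_per_mm * depth)
        aperture = ptv_rot.any(axis=0)
        if margin_vox:
            aperture = ndimage.binary_dilation(aperture, iterations=margin_vox)
        beam *= aperture[None, :, :]
        if sigma_vox > 0:
            beam = ndimage.gaussian_filter(beam, sigma=(0.0, sigma_vox, sigma_vox))
        total += _rotate(beam, -angle, order=1, cval=0.0)

    if spec.mode == "medium":
        f_red = np.asarray([a[0] for a in spec.medium_factor])
        f_val = np.asarray([a[1] for a in spec.medium_factor])
        total *= np.interp(red, f_red, f_val)

    ptv_mean = total[ptv_d.values].mean()
    if ptv_mean <= 0:
        raise ValueError("PTV outside beam coverage: zero PTV dose before scaling")
    total *= prescription_gy / ptv_mean
    return ScalarVolume(grid, np.maximum(total, 0.0))
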