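"""Bone volume ratio: fraction of the PTV labeled bone on the synthetic CT.

The ratio of the volume of {sCT ≥ threshold} ∩ PTV to the PTV volume is a
case-level predictor of the dosimetric accuracy of a synthetic CT: targets
containing (or mislabeled as containing) more bone are more exposed to
HU-labeling errors.  Bone is tissue at or above 100 HU *on the sCT*, so the
computation lives on the sCT grid; a PTV supplied on another grid is
resampled there by nearest-neighbor.

No acceptability cut-off is shipped: the ratio is reported as-is and sites
calibrate their own thresholds against their desired gamma passing rates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .agreement import BONE_THRESHOLD_HU
from .grids import (
    BinaryMask,
    EmptyStructureError,
    ScalarVolume,
    mask_volume,
    resample,
    threshold_mask,
)

__all__ = ["BvrValue", "bone_volume_ratio"]


@dataclass(frozen=True)
class BvrValue:
    ratio: float
    bone_volume_cm3: float
    ptv_volume_cm3: float
    threshold_hu: float

    def to_dict(self) -> dict:
        return {
            "bone_volume_ratio": self.ratio,
            "bone_volume_cm3": self.bone_volume_cm3,
            "ptv_volume_cm3": self.ptv_volume_cm3,
            "threshold_hu": self.threshold_hu,
        }


def bone_volume_ratio(
    sct: ScalarVolume,
    ptv: BinaryMask,
    threshold_hu: float = BONE_THRESHOLD_HU,
) -> BvrValue:
    """Bone volume ratio of the PTV on the sCT grid."""
    if not ptv.grid.same_geometry(sct.grid):
        ptv = resample(ptv, sct.grid, mode="nearest")
    if ptv.voxel_count == 0:
        raise EmptyStructureError("bone_volume_ratio: PTV mask is empty")
    bone_in_ptv = threshold_mask(sct, threshold_hu, within=ptv)
    bone_cm3 = mask_volume(bone_in_ptv)
    ptv_cm3 = mask_volume(ptv)
    return BvrValue(
        ratio=bone_cm3 / ptv_cm3,
        bone_volume_cm3=bone_cm3,
        ptv_volume_cm3=ptv_cm3,
        threshold_hu=float(threshold_hu),
    )
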