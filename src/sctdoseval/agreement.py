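"""CT-number agreement between synthetic CT and planning CT.

Metrics follow the standard sCT-QA conventions: per-region mean absolute
error (MAE) and mean error (ME) of the HU difference, and the Dice
similarity coefficient (DSC) of the skull-bone segmentations obtained by
thresholding at 100 HU within the skull region.

Sign convention: ME = mean(sCT − CT), so a synthetic CT that underestimates
HU comes out negative.  All metrics are evaluated on the planning-CT grid
(the reference modality); the sCT is resampled trilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    BinaryMask,
    EmptyStructureError,
    ScalarVolume,
    _require_same_grid,
    resample,
    threshold_mask,
)

__all__ = [
    "AgreementReport",
    "mean_absolute_error",
    "mean_error",
    "dice",
    "agreement_report",
    "BONE_THRESHOLD_HU",
]

#: HU threshold defining "bone" throughout the package.
BONE_THRESHOLD_HU = 100.0


def _region_diffs(ct: ScalarVolume, sct: ScalarVolume, region: BinaryMask) -> np.ndarray:
    _require_same_grid(ct, sct, "agreement")
    _require_same_grid(ct, region, "agreement")
    if region.voxel_count == 0:
        raise EmptyStructureError("agreement region mask is empty")
    return (
        sct.values[region.values].astype(np.float64)
        - ct.values[region.values].astype(np.float64)
    )


def mean_absolute_error(ct: ScalarVolume, sct: ScalarVolume, region: BinaryMask) -> float:
    """Mean |sCT − CT| (HU) over a region."""
    return float(np.abs(_region_diffs(ct, sct, region)).mean())


def mean_error(ct: ScalarVolume, sct: ScalarVolume, region: BinaryMask) -> float:
    """Mean (sCT − CT) (HU) over a region; negative = sCT underestimates."""
    return float(_region_diffs(ct, sct, region).mean())


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    _require_same_grid(a, b, "dice")
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        raise EmptyStructureError("dice undefined: both masks are empty")
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


@dataclass
class AgreementReport:
    """Per-region MAE/ME plus the skull-bone DSC.

    ``regions`` maps region name -> {"mae_hu", "me_hu"}.  The recorded sign
    convention is sCT − CT.
    """

    regions: dict[str, dict[str, float]] = field(default_factory=dict)
    skull_dsc: float = float("nan")
    sign_convention: str = "sct_minus_ct"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": name, "mae_hu": v["mae_hu"], "me_hu": v["me_hu"]}
            for name, v in self.regions.items()
        ]
        return pd.DataFrame(rows)


def agreement_report(
    ct: ScalarVolume,
    sct: ScalarVolume,
    masks: dict[str, BinaryMask],
    bone_threshold_hu: float = BONE_THRESHOLD_HU,
) -> AgreementReport:
    """Full image-agreement evaluation of one case.

    ``masks`` must contain ``body``, ``brain`` and ``skull_region`` on the
    CT grid.  MAE/ME are reported for body, brain and the skull-bone subset
    of the skull region (CT ≥ threshold); DSC compares the CT- and
    sCT-derived skull-bone masks within the skull region.
    """
    for name in ("body", "brain", "skull_region"):
        if name not in masks:
            raise KeyError(f"missing region mask: {name!r}")
    if not sct.grid.same_geometry(ct.grid):
        sct = resample(sct, ct.grid, mode="trilinear")

    skull_region = masks["skull_region"]
    ct_bone = threshold_mask(ct, bone_threshold_hu, within=skull_region)
    sct_bone = threshold_mask(sct, bone_threshold_hu, within=skull_region)

    report = AgreementReport(skull_dsc=dice(ct_bone, sct_bone))
    for name, region in (
        ("body", masks["body"]),
        ("brain", masks["brain"]),
        ("skull_bone", ct_bone),
        ("skull_region", skull_region),
    ):
        report.regions[name] = {
            "mae_hu": mean_absolute_error(ct, sct, region),
            "me_hu": mean_error(ct, sct, region),
        }
    return report
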