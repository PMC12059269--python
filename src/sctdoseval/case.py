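"""The per-patient data bundle shared by the pipeline and the generator."""

from __future__ import annotations

from dataclasses import dataclass, field

from .grids import BinaryMask, ScalarVolume

__all__ = ["PatientCase", "REQUIRED_MASKS"]

REQUIRED_MASKS = ("body", "brain", "skull_region", "ptv")


@dataclass
class PatientCase:
    """Paired CT/sCT images, structure masks, and paired dose volumes.

    Masks live on the planning-CT grid; dose volumes share one dose grid.
    ``truth`` carries generator ground-truth values for synthetic cases (and
    is empty for file-based cases); ``extras`` holds auxiliary volumes such
    as dose pairs computed in the other reporting mode.
    """

    case_id: str
    ct: ScalarVolume
    sct: ScalarVolume
    masks: dict[str, BinaryMask]
    reference_dose: ScalarVolume | None
    evaluated_dose: ScalarVolume | None
    prescription_gy: float
    truth: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def validate(self, required_masks=REQUIRED_MASKS) -> None:
        if self.prescription_gy <= 0:
            raise ValueError(f"case {self.case_id}: prescription must be positive")
        missing = [m for m in required_masks if m not in self.masks]
        if missing:
            raise KeyError(
                f"case {self.case_id}: missing structure mask(s): {', '.join(missing)}"
            )
        for name in required_masks:
            if self.masks[name].voxel_count == 0:
                raise ValueError(f"case {self.case_id}: mask {name!r} is empty")
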