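"""Seeded synthetic cohorts emulating a post-surgical brain-RT population.

Each case is a head phantom whose PTV is placed along a seeded direction and
pushed toward (or into) bone until a target true-bone fraction is reached by
bisection — deep-brain targets carry essentially no bone, skull-base and
sinus-adjacent targets up to ~half of their volume.  Target fractions span
0.02–0.48 across the cohort, PTV volumes shrink from ~400 to ~45 cm³ as the
bone fraction grows (large targets cannot geometrically be half bone), and
prescriptions are drawn from 40–60 Gy.

The severity link couples sCT corruption to anatomy: the bone/air-interface
mislabel probability grows linearly with the case's analytic bone fraction,
so bone-adjacent targets both *have* high bone volume ratios and *suffer*
larger sCT dose errors — the mechanism the bone-volume-ratio metric is
designed to flag.  The case with the highest bone fraction additionally
receives the synthetic implant plate (mislabeled as bone), emulating the
worst-case skull-reconstruction failure.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from ..case import PatientCase
from ..grids import VolumeGrid
from .dose import DoseModelSpec, compute_dose, dose_grid_for
from .phantom import (
    CorruptionSpec,
    PhantomGeometry,
    PhantomSpec,
    corrupt_to_sct,
    default_ct_grid,
    default_sct_grid,
)

__all__ = ["CohortDesign", "make_cohort", "default_severity_link"]


@dataclass(frozen=True)
class CohortDesign:
    """Cohort-level generator settings (the study conditions)."""

    bone_fraction_range: tuple[float, float] = (0.02, 0.48)
    ptv_volume_range_cm3: tuple[float, float] = (45.0, 400.0)
    prescription_range_gy: tuple[float, float] = (40.0, 60.0)
    base_noise_sigma_hu: float = 17.0
    interface_shell_mm: float = 1.5
    severity_slope: float = 1.4       # mislabel probability per unit bone fraction
    severity_floor: float = 0.08
    severity_cap: float = 0.85
    implant_for_max_bone_case: bool = True


def default_severity_link(bone_fraction: float, design: CohortDesign) -> float:
    """Interface mislabel probability as a function of true bone fraction."""
    p = design.severity_floor + design.severity_slope * bone_fraction
    return float(np.clip(p, 0.0, design.severity_cap))


def _ptv_semiaxes(volume_cm3: float, rng) -> tuple[float, float, float]:
    r = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    u = rng.uniform(0.85, 1.18, size=2)
    return (r * u[0], r * u[1], r / (u[0] * u[1]))


def _random_direction(rng, downward_weight: float) -> np.ndarray:
    """Unit vector, biased toward the skull base as ``downward_weight`` → 1."""
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    v = (1.0 - downward_weight) * v + downward_weight * np.array([0.0, 0.0, -1.0])
    return v / np.linalg.norm(v)


def _coarse_bone_fraction(geom: PhantomGeometry) -> float:
    return geom.bone_fraction_in_ptv(supersample_spacing=(2.0, 2.0, 2.0))


def _place_ptv(
    base: PhantomSpec, semi, direction, f_target: float, feature_seed: int
) -> PhantomSpec:
    """Bisect the PTV center along ``direction`` to hit the target bone
    fraction, keeping the PTV inside the head."""
    head = np.asarray(base.head_semiaxes)
    s = np.asarray(semi)
    # farthest center along `direction` keeping the PTV bounding box inside
    d = np.asarray(direction)
    with np.errstate(divide="ignore"):
        t_limit = np.min(np.where(np.abs(d) > 1e-9, (head - s) / np.abs(d), np.inf))
    # small pull-back keeps the bounding box strictly inside under roundoff
    t_limit = float(max(t_limit - 1e-3, 0.0))

    def frac_at(t: float) -> float:
        spec = dataclasses.replace(
            base, ptv_center_mm=tuple(t * d), ptv_semiaxes_mm=tuple(s)
        )
        return _coarse_bone_fraction(PhantomGeometry(spec, seed=feature_seed))

    lo, hi = 0.0, t_limit
    f_hi = frac_at(hi)
    if f_hi <= f_target:
        t_best = hi  # clamp: deepest achievable bone contact for this geometry
    else:
        for _ in range(14):
            mid = 0.5 * (lo + hi)
            if frac_at(mid) < f_target:
                lo = mid
            else:
                hi = mid
        t_best = hi
    return dataclasses.replace(
        base, ptv_center_mm=tuple(t_best * d), ptv_semiaxes_mm=tuple(s)
    )


def make_cohort(
    n: int = 20,
    seed: int = 7,
    dose_mode: str = "medium",
    design: CohortDesign | None = None,
    severity_link=default_severity_link,
    severity_scale: float = 1.0,
    with_dose: bool = True,
    extra_dose_modes: tuple[str, ...] = (),
) -> list[PatientCase]:
    """Generate ``n`` seeded cases.  Same (n, seed, settings) → same cohort.

    ``severity_scale`` multiplies the severity-linked mislabel probability
    (0 disables all corruption, noise included).  ``extra_dose_modes`` adds
    reference/evaluated dose pairs for other reporting modes under
    ``case.extras['dose_<mode>']``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)

    f_lo, f_hi = design.bone_fraction_range
    f_targets = np.linspace(f_lo, f_hi, n) + rng.normal(0.0, 0.01, size=n)
    f_targets = np.clip(f_targets, 0.005, 0.55)
    implant_case = int(np.argmax(f_targets)) if design.implant_for_max_bone_case else -1

    v_lo, v_hi = design.ptv_volume_range_cm3
    cases = []
    for i in range(n):
        f_t = float(f_targets[i])
        # large targets cannot be half bone: volume shrinks with bone fraction
        w = (f_t - f_lo) / max(f_hi - f_lo, 1e-9)
        vol = float(
            np.exp(np.log(v_hi) + w * (np.log(v_lo) - np.log(v_hi)))
            * np.exp(rng.normal(0.0, 0.08))
        )
        semi = _ptv_semiaxes(vol, rng)
        direction = _random_direction(rng, downward_weight=0.25 + 0.6 * w)
        rx = float(rng.choice(np.arange(design.prescription_range_gy[0],
                                        design.prescription_range_gy[1] + 1, 2.0)))
        n_holes = int(rng.integers(1, 4))
        n_screws = int(rng.integers(1, 4))

        base = PhantomSpec(
            prescription_gy=rx,
            n_drill_holes=n_holes,
            n_screws=n_screws,
            has_implant=(i == implant_case),
        )
        feature_seed = int(seeds[2 * i])
        spec = _place_ptv(base, semi, direction, f_t, feature_seed)
        geom = PhantomGeometry(spec, seed=feature_seed)
        ct = geom.render_hu(default_ct_grid(spec))
        masks = geom.render_masks(ct.grid)
        f_true = geom.bone_fraction_in_ptv()

        p_interface = severity_scale * severity_link(f_true, design)
        cspec = CorruptionSpec(
            noise_sigma_hu=design.base_noise_sigma_hu * min(severity_scale, 1.0)
            if severity_scale > 0
            else 0.0,
            interface_mislabel_prob=min(p_interface, 1.0),
            interface_shell_mm=design.interface_shell_mm,
            mislabel_drill_holes=severity_scale > 0,
            mislabel_screws=severity_scale > 0,
            mislabel_implant=severity_scale > 0,
            seed=int(seeds[2 * i + 1]),
        )
        sct = corrupt_to_sct(ct, geom, cspec, target_grid=default_sct_grid(spec))

        ref_dose = eval_dose = None
        extras: dict = {}
        if with_dose:
            dgrid = dose_grid_for(ct.grid, DoseModelSpec().dose_grid_spacing_mm)
            for mode in (dose_mode, *extra_dose_modes):
                dspec = DoseModelSpec(mode=mode)
                ref = compute_dose(ct, masks["ptv"], dspec, rx, dose_grid=dgrid)
                ev = compute_dose(sct, masks["ptv"], dspec, rx, dose_grid=dgrid)
                if mode == dose_mode:
                    ref_dose, eval_dose = ref, ev
                else:
                    extras[f"dose_{mode}"] = (ref, ev)

        cases.append(
            PatientCase(
                case_id=f"case{i:03d}",
                ct=ct,
                sct=sct,
                masks=masks,
                reference_dose=ref_dose,
                evaluated_dose=eval_dose,
                prescription_gy=rx,
                truth={
                    "bone_fraction_in_ptv": f_true,
                    "target_bone_fraction": f_t,
                    "interface_mislabel_prob": float(min(p_interface, 1.0)),
                },
                extras=extras,
            )
        )
    return cases
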