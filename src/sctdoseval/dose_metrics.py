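"""Cumulative DVHs and plan-quality metrics.

The cumulative DVH of a structure gives, per dose level d, the fraction of
the structure's volume receiving at least d.  From it come the standard
plan metrics:

* Dx — dose received by at least x% of the structure (D2, D50, D95, D98),
* Vx — percent of the structure receiving at least a given dose (V95 uses
  95% of the prescription),
* HI = (D2 − D98) / D50 × 100 (heterogeneity; 0 for a uniform dose),
* CI = V_RI / TV (RTOG conformity; V_RI = body volume at or above the
  prescription isodose, TV = PTV volume),
* Dmax / Dmean — single-voxel maximum and arithmetic-mean structure dose.

Dmax is the single-voxel maximum (no near-maximum D0.03cc surrogate), which
keeps every metric exactly reproducible by a full sort of structure doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import (
    BinaryMask,
    EmptyStructureError,
    ScalarVolume,
    _require_same_grid,
    mask_volume,
    threshold_mask,
)

__all__ = [
    "DVH",
    "PlanMetrics",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "point_metrics",
    "homogeneity_index",
    "conformity_index",
    "compute_plan_metrics",
    "metric_difference",
    "DEFAULT_BIN_FRACTION",
]

#: Default DVH bin width as a fraction of the prescription dose (0.05%),
#: well below the 0.1% granularity at which metric differences are read.
DEFAULT_BIN_FRACTION = 5e-4


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    edges_gy: np.ndarray      # uniform bin edges, starting at 0
    cumulative: np.ndarray    # fraction of volume with dose >= edge, in [0, 1]

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.edges_gy.shape != self.cumulative.shape:
            raise ValueError("edges and cumulative curve must have equal length")

    @property
    def bin_width_gy(self) -> float:
        return float(self.edges_gy[1] - self.edges_gy[0])


def cumulative_dvh(
    dose: ScalarVolume, structure: BinaryMask, bin_width_gy: float
) -> DVH:
    """Cumulative DVH with uniform bins of ``bin_width_gy``."""
    _require_same_grid(dose, structure, "cumulative_dvh")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = dose.values[structure.values].astype(np.float64)
    if doses.size == 0:
        raise EmptyStructureError("cumulative_dvh: structure mask is empty")
    top = float(doses.max())
    n_bins = int(np.ceil(top / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    # fraction of voxels with dose >= edge
    counts, _ = np.histogram(doses, bins=np.append(edges, np.inf))
    cum = counts[::-1].cumsum()[::-1] / doses.size
    return DVH(structure="", edges_gy=edges, cumulative=cum)


def dose_at_volume(dvh: DVH, x_pct: float) -> float:
    """Dx: dose (Gy) received by at least ``x_pct``% of the structure."""
    if not 0.0 < x_pct < 100.0:
        raise ValueError(f"x must be in (0, 100), got {x_pct}")
    frac = x_pct / 100.0
    cum = dvh.cumulative
    edges = dvh.edges_gy
    # The binned cumulative curve is a step function (all doses inside a bin
    # are represented by its lower edge), so its exact inverse is the largest
    # edge still covering the requested fraction.  This keeps Dx exact on
    # piecewise-constant dose distributions (uniform dose -> HI = 0) and
    # within one bin width otherwise.
    covered = np.nonzero(cum >= frac)[0]
    if covered.size == 0:
        return float(edges[0])
    return float(edges[covered[-1]])


def volume_at_dose(dvh: DVH, d_gy: float) -> float:
    """Vd: percent of the structure receiving at least ``d_gy`` Gy."""
    if d_gy < 0:
        raise ValueError("dose level must be >= 0")
    if d_gy >= dvh.edges_gy[-1]:
        return float(100.0 * dvh.cumulative[-1]) if d_gy <= dvh.edges_gy[-1] else 0.0
    return float(100.0 * np.interp(d_gy, dvh.edges_gy, dvh.cumulative))


def point_metrics(dose: ScalarVolume, structure: BinaryMask) -> dict[str, float]:
    """Single-voxel Dmax and arithmetic Dmean (Gy) within a structure."""
    _require_same_grid(dose, structure, "point_metrics")
    doses = dose.values[structure.values]
    if doses.size == 0:
        raise EmptyStructureError("point_metrics: structure mask is empty")
    return {"Dmax_gy": float(doses.max()), "Dmean_gy": float(doses.mean())}


def homogeneity_index(dvh: DVH) -> float:
    """HI = (D2 − D98) / D50 × 100; 0 for a perfectly uniform dose."""
    d50 = dose_at_volume(dvh, 50.0)
    if d50 <= 0:
        raise ValueError("homogeneity index undefined: D50 = 0")
    return (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / d50 * 100.0


def conformity_index(
    dose: ScalarVolume,
    ptv: BinaryMask,
    body: BinaryMask,
    prescription_gy: float,
) -> float:
    """RTOG CI = V_RI / TV, with V_RI restricted to the body mask."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    if ptv.voxel_count == 0:
        raise EmptyStructureError("conformity_index: PTV mask is empty")
    isodose = threshold_mask(dose, prescription_gy, within=body)
    return mask_volume(isodose) / mask_volume(ptv)


# ---------------------------------------------------------------------------
# Per-plan metric bundles

#: serial organs are reported by Dmax, parallel organs by Dmean
SERIAL_OARS = ("brainstem", "optic_chiasm", "lens_l", "lens_r",
               "optic_nerve_l", "optic_nerve_r")
PARALLEL_OARS = ("cochlea_l", "cochlea_r")


@dataclass
class PlanMetrics:
    """PTV and OAR dose metrics of one plan.

    PTV dose levels are stored in Gy (with the prescription alongside) so
    they can be reported either as percent-of-prescription or relative to a
    comparison plan; OAR metrics are stored in Gy and reported in cGy.
    """

    prescription_gy: float
    ptv_dmax_gy: float
    ptv_dmean_gy: float
    ptv_d95_gy: float
    ptv_v95_pct: float
    hi: float
    ci: float
    oar_dose_gy: dict[str, float] = field(default_factory=dict)  # name -> Dmax/Dmean

    def ptv_pct(self, value_gy: float) -> float:
        return 100.0 * value_gy / self.prescription_gy


def compute_plan_metrics(
    dose: ScalarVolume,
    structures: dict[str, BinaryMask],
    prescription_gy: float,
    bin_width_gy: float | None = None,
    serial_oars: tuple[str, ...] = SERIAL_OARS,
    parallel_oars: tuple[str, ...] = PARALLEL_OARS,
) -> PlanMetrics:
    """Evaluate the full PTV/OAR metric set on one dose distribution.

    ``structures`` must contain ``ptv`` and ``body``; OARs that are absent
    from the dict are skipped.
    """
    for required in ("ptv", "body"):
        if required not in structures:
            raise KeyError(f"missing required structure mask: {required!r}")
    bw = bin_width_gy or DEFAULT_BIN_FRACTION * prescription_gy
    ptv = structures["ptv"]
    dvh = cumulative_dvh(dose, ptv, bw)
    pm = point_metrics(dose, ptv)
    oar_dose: dict[str, float] = {}
    for name in serial_oars:
        if name in structures:
            oar_dose[name] = point_metrics(dose, structures[name])["Dmax_gy"]
    for name in parallel_oars:
        if name in structures:
            oar_dose[name] = point_metrics(dose, structures[name])["Dmean_gy"]
    return PlanMetrics(
        prescription_gy=prescription_gy,
        ptv_dmax_gy=pm["Dmax_gy"],
        ptv_dmean_gy=pm["Dmean_gy"],
        ptv_d95_gy=dose_at_volume(dvh, 95.0),
        ptv_v95_pct=volume_at_dose(dvh, 0.95 * prescription_gy),
        hi=homogeneity_index(dvh),
        ci=conformity_index(dose, ptv, structures["body"], prescription_gy),
        oar_dose_gy=oar_dose,
    )


def metric_difference(
    reference: PlanMetrics,
    evaluated: PlanMetrics,
    normalizer: str = "prescription",
) -> dict[str, float]:
    """Reference-minus-evaluated metric differences.

    PTV dose metrics come out in percent — of the prescription dose
    (default) or of the evaluated plan's own metric value
    (``normalizer="evaluated"``); V95 differences are in percentage points,
    OAR differences in cGy, HI/CI raw.
    """
    if abs(reference.prescription_gy - evaluated.prescription_gy) > 1e-9:
        raise ValueError("prescriptions differ between the two metric sets")
    if set(reference.oar_dose_gy) != set(evaluated.oar_dose_gy):
        raise ValueError(
            f"structure mismatch: {sorted(reference.oar_dose_gy)} vs "
            f"{sorted(evaluated.oar_dose_gy)}"
        )

    def pct(ref_gy: float, ev_gy: float) -> float:
        if normalizer == "prescription":
            return 100.0 * (ref_gy - ev_gy) / reference.prescription_gy
        if normalizer == "evaluated":
            return 100.0 * (ref_gy - ev_gy) / ev_gy
        raise ValueError(f"unknown normalizer {normalizer!r}")

    diffs = {
        "ptv_dmax_pct": pct(reference.ptv_dmax_gy, evaluated.ptv_dmax_gy),
        "ptv_dmean_pct": pct(reference.ptv_dmean_gy, evaluated.ptv_dmean_gy),
        "ptv_d95_pct": pct(reference.ptv_d95_gy, evaluated.ptv_d95_gy),
        "ptv_v95_pct": reference.ptv_v95_pct - evaluated.ptv_v95_pct,
        "hi": reference.hi - evaluated.hi,
        "ci": reference.ci - evaluated.ci,
    }
    for name in reference.oar_dose_gy:
        diffs[f"{name}_cgy"] = 100.0 * (
            reference.oar_dose_gy[name] - evaluated.oar_dose_gy[name]
        )
    return diffs
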