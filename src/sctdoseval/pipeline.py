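"""End-to-end orchestration: per-case evaluation and cohort studies.

The pipeline adds no computation of its own — every reported number is
reproducible by calling the individual modules with the same inputs.  All
outputs (CSV + JSON) are written with fixed float formatting and sorted
keys, so a fixed configuration and seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import agreement_report
from .bvr import bone_volume_ratio
from .case import REQUIRED_MASKS, PatientCase
from .cohort_stats import CaseResult, CohortSummary, summarize_cohort
from .dose_metrics import (
    DEFAULT_BIN_FRACTION,
    compute_plan_metrics,
    metric_difference,
)
from .gamma import GammaCriteria, gamma_suite
from .grids import resample
from .synthetic import make_cohort

__all__ = ["RunConfig", "CaseReport", "run_case", "run_cohort", "bvr_gamma_table"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """One run's worth of settings; every clinical default is visible here."""

    input_mode: str = "synthetic"            # "synthetic" or "files"
    n_cases: int = 20
    seed: int = 7
    dose_mode: str = "medium"
    severity_scale: float = 1.0
    #: (dose difference %, DTA mm) pairs
    gamma_criteria: tuple[tuple[float, float], ...] = (
        (3.0, 2.0), (3.0, 1.0), (2.0, 1.0), (1.0, 1.0),
    )
    low_dose_threshold_pct: float = 10.0
    normalization: str = "global-max"
    dvh_bin_fraction: float = DEFAULT_BIN_FRACTION
    bone_threshold_hu: float = 100.0
    diff_normalizer: str = "prescription"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.gamma_criteria:
            raise ValueError("gamma criteria list must be non-empty")
        if self.low_dose_threshold_pct < 0:
            raise ValueError("low-dose threshold must be >= 0")

    def criteria(self) -> tuple[GammaCriteria, ...]:
        return tuple(
            GammaCriteria(dd, dta, self.low_dose_threshold_pct, self.normalization)
            for dd, dta in self.gamma_criteria
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma_criteria"] = [list(c) for c in self.gamma_criteria]
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (JSON is a YAML subset and is accepted too)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gamma_criteria" in raw:
            raw["gamma_criteria"] = tuple(
                (float(a), float(b)) for a, b in raw["gamma_criteria"]
            )
        return cls(**raw)


@dataclass
class CaseReport:
    """All per-case evaluation products."""

    case_id: str
    agreement: object
    metrics_reference: object
    metrics_evaluated: object
    metric_differences: dict[str, float]
    gamma_table: pd.DataFrame
    bvr: object

    def to_case_result(self) -> CaseResult:
        rates = {
            (row.dose_difference_pct, row.dta_mm, row.region): row.passing_rate_pct
            for row in self.gamma_table.itertuples()
        }
        return CaseResult(
            case_id=self.case_id,
            metric_differences=self.metric_differences,
            gamma_rates=rates,
            bone_volume_ratio=self.bvr.ratio,
        )


def _dose_grid_masks(case: PatientCase, dose_grid):
    return {
        name: resample(mask, dose_grid, mode="nearest")
        for name, mask in case.masks.items()
    }


def run_case(config: RunConfig, case: PatientCase, out_dir=None) -> CaseReport:
    """Evaluate one case: agreement, plan metrics, gamma suite, BVR."""
    case.validate(required_masks=REQUIRED_MASKS)
    if case.reference_dose is None or case.evaluated_dose is None:
        raise ValueError(f"case {case.case_id}: missing dose volumes")

    agreement = agreement_report(
        case.ct, case.sct, case.masks, bone_threshold_hu=config.bone_threshold_hu
    )

    dmasks = _dose_grid_masks(case, case.reference_dose.grid)
    bw = config.dvh_bin_fraction * case.prescription_gy
    m_ref = compute_plan_metrics(
        case.reference_dose, dmasks, case.prescription_gy, bin_width_gy=bw
    )
    m_eval = compute_plan_metrics(
        case.evaluated_dose, dmasks, case.prescription_gy, bin_width_gy=bw
    )
    diffs = metric_difference(m_ref, m_eval, normalizer=config.diff_normalizer)

    gtable = gamma_suite(
        case.reference_dose,
        case.evaluated_dose,
        dmasks["ptv"],
        criteria_list=config.criteria(),
        prescription_gy=case.prescription_gy,
    )
    bvr = bone_volume_ratio(case.sct, case.masks["ptv"], config.bone_threshold_hu)

    report = CaseReport(
        case_id=case.case_id,
        agreement=agreement,
        metrics_reference=m_ref,
        metrics_evaluated=m_eval,
        metric_differences=diffs,
        gamma_table=gtable,
        bvr=bvr,
    )
    if out_dir is not None:
        _write_case_report(report, Path(out_dir))
    return report


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _write_case_report(report: CaseReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.agreement.to_frame().to_csv(
        out_dir / "agreement.csv", index=False, float_format=_FLOAT_FMT
    )
    report.gamma_table.to_csv(
        out_dir / "gamma.csv", index=False, float_format=_FLOAT_FMT
    )
    _json_dump(
        {
            "case_id": report.case_id,
            "skull_dsc": report.agreement.skull_dsc,
            "metric_differences": report.metric_differences,
            "bone_volume_ratio": report.bvr.to_dict(),
        },
        out_dir / "case.json",
    )


def run_cohort(
    config: RunConfig, cases: list[PatientCase] | None = None
) -> tuple[CohortSummary, list[CaseReport]]:
    """Evaluate a cohort and aggregate its statistics.

    With ``cases=None`` and synthetic input mode, the seeded default cohort
    is generated from the config.  A failing case aborts the run with its id.
    """
    if cases is None:
        if config.input_mode != "synthetic":
            raise ValueError("input_mode='files' requires an explicit case list")
        cases = make_cohort(
            n=config.n_cases,
            seed=config.seed,
            dose_mode=config.dose_mode,
            severity_scale=config.severity_scale,
        )
    if len(cases) < 3:
        raise ValueError("cohort statistics need at least 3 cases")

    out_root = Path(config.output_dir) if config.output_dir else None
    reports = []
    for case in cases:
        try:
            out_dir = out_root / case.case_id if out_root else None
            reports.append(run_case(config, case, out_dir=out_dir))
        except Exception as exc:
            raise RuntimeError(f"case {case.case_id} failed: {exc}") from exc

    summary = summarize_cohort([r.to_case_result() for r in reports])
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
        summary.metrics.to_csv(
            out_root / "cohort_metrics.csv", index=False, float_format=_FLOAT_FMT
        )
        summary.gamma_means.to_csv(
            out_root / "cohort_gamma_means.csv", index=False, float_format=_FLOAT_FMT
        )
        summary.correlations.to_csv(
            out_root / "cohort_correlations.csv", index=False, float_format=_FLOAT_FMT
        )
        _json_dump(
            {"config": config.to_dict(), "summary": _round_tree(summary.to_dict())},
            out_root / "cohort_summary.json",
        )
    return summary, reports


def bvr_gamma_table(
    cases: list[PatientCase],
    criteria: GammaCriteria | None = None,
) -> pd.DataFrame:
    """Per-case bone volume ratio and PTV passing rate(s) for one criterion.

    The core of the predictor study: for every case the PTV-restricted gamma
    passing rate is computed for the case's dose pair and for any extra dose
    modes carried in ``case.extras``; columns are ``rate`` and
    ``rate_<mode>``.
    """
    from .gamma import gamma_index_map, passing_rate

    crit = criteria or GammaCriteria(1.0, 1.0)
    rows = []
    for case in cases:
        ptv_d = resample(case.masks["ptv"], case.reference_dose.grid, mode="nearest")
        row = {
            "case_id": case.case_id,
            "bone_volume_ratio": bone_volume_ratio(
                case.sct, case.masks["ptv"]
            ).ratio,
            "rate": passing_rate(
                gamma_index_map(
                    case.reference_dose, case.evaluated_dose, crit, region=ptv_d
                )
            ),
        }
        for key, (ref, ev) in case.extras.items():
            if key.startswith("dose_"):
                row[f"rate_{key[5:]}"] = passing_rate(
                    gamma_index_map(ref, ev, crit, region=ptv_d)
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _round_tree(obj):
    """Round floats for stable JSON serialization (12 significant digits)."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_tree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v) for v in obj]
    return obj
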