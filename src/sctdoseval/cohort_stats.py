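"""Cohort-level statistics.

Paired per-case metric differences are tested with the two-sided Wilcoxon
signed-rank test; the bone volume ratio is correlated against gamma passing
rates with the Pearson test.  Wilcoxon p-values are exact (full signed-rank
null distribution) whenever n ≤ 25 with no ties among the non-zero absolute
differences, otherwise a tie-corrected normal approximation with continuity
correction is used.  Zero differences are dropped before ranking (classical
treatment); Pratt's method is available via ``zero_method="pratt"``.

A Holm-adjusted p-value column is emitted alongside the raw p-values for
transparency, but significance flags use the raw two-sided 0.05 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WilcoxonResult",
    "CaseResult",
    "CohortSummary",
    "wilcoxon_signed_rank",
    "pearson_correlation",
    "summarize_cohort",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float          # NaN when degenerate
    p_value: float
    n_used: int               # sample size after zero handling
    exact: bool
    degenerate: bool = False


def wilcoxon_signed_rank(
    differences, zero_method: str = "drop", exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    ``zero_method="drop"`` removes zero differences before ranking;
    ``"pratt"`` keeps them in the ranking.  An all-zero input is flagged
    degenerate with p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1D sequence")
    if zero_method not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d[d != 0.0]
    if nonzero.size == 0:
        return WilcoxonResult(float("nan"), 1.0, 0, exact=False, degenerate=True)

    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    use_exact = (
        zero_method == "drop" and nonzero.size <= exact_max_n and not has_ties
    )
    if zero_method == "drop":
        sample, scipy_zero = nonzero, "wilcox"
    else:
        sample, scipy_zero = d, "pratt"
    res = sps.wilcoxon(
        sample,
        zero_method=scipy_zero,
        alternative="two-sided",
        correction=not use_exact,
        method="exact" if use_exact else "approx",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_used=int(nonzero.size),
        exact=use_exact,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson R with the two-sided t-test p-value (n − 2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined: zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CaseResult:
    """Per-case quantities feeding the cohort summary."""

    case_id: str
    metric_differences: dict[str, float]
    gamma_rates: dict[tuple[float, float, str], float]  # (dd%, dta mm, region) -> %
    bone_volume_ratio: float


@dataclass
class CohortSummary:
    """Mean/range/Wilcoxon table, mean gamma rates, and BVR correlations."""

    n_cases: int
    metrics: pd.DataFrame       # metric, mean_difference, min, max, p, p_holm, significant
    gamma_means: pd.DataFrame   # dd, dta, region, mean passing rate
    correlations: pd.DataFrame  # dd, dta, region, pearson_r, p, degenerate

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "metrics": self.metrics.to_dict(orient="records"),
            "gamma_means": self.gamma_means.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
        }


def summarize_cohort(cases: list[CaseResult]) -> CohortSummary:
    """Aggregate per-case results into the cohort-level tables."""
    if len(cases) < 3:
        raise ValueError("need at least 3 cases for cohort statistics")
    metric_names = list(cases[0].metric_differences)
    gamma_keys = list(cases[0].gamma_rates)
    for c in cases[1:]:
        if list(c.metric_differences) != metric_names:
            raise ValueError(
                f"inconsistent metric sets across cases (case {c.case_id})"
            )
        if list(c.gamma_rates) != gamma_keys:
            raise ValueError(
                f"inconsistent gamma settings across cases (case {c.case_id})"
            )

    rows = []
    for name in metric_names:
        vals = np.array([c.metric_differences[name] for c in cases])
        w = wilcoxon_signed_rank(vals)
        rows.append(
            {
                "metric": name,
                "mean_difference": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "p_value": w.p_value,
                "degenerate": w.degenerate,
            }
        )
    metrics = pd.DataFrame(rows)
    metrics["p_holm"] = multipletests(metrics["p_value"], method="holm")[1]
    metrics["significant"] = metrics["p_value"] < SIGNIFICANCE_LEVEL

    bvr = np.array([c.bone_volume_ratio for c in cases])
    grows, crows = [], []
    for dd, dta, region in gamma_keys:
        rates = np.array([c.gamma_rates[(dd, dta, region)] for c in cases])
        grows.append(
            {
                "dose_difference_pct": dd,
                "dta_mm": dta,
                "region": region,
                "mean_passing_rate_pct": float(rates.mean()),
            }
        )
        degenerate = np.ptp(rates) == 0 or np.ptp(bvr) == 0
        if degenerate:
            r_val, p_val = float("nan"), float("nan")
        else:
            r_val, p_val = pearson_correlation(bvr, rates)
        crows.append(
            {
                "dose_difference_pct": dd,
                "dta_mm": dta,
                "region": region,
                "pearson_r": r_val,
                "p_value": p_val,
                "degenerate": bool(degenerate),
            }
        )
    return CohortSummary(
        n_cases=len(cases),
        metrics=metrics,
        gamma_means=pd.DataFrame(grows),
        correlations=pd.DataFrame(crows),
    )
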