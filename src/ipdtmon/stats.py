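"""Nonparametric statistics and cohort summaries over per-pair results.

The clinical questions are comparative: is the absorption increase during iPDT
larger for fiber pairs whose light transmission zone intersects a T1
hyperintensity lesion, and does the lesion's "strength" scale with the
absorption change?  Group comparisons use the Mann-Whitney U test (exact null
distribution for small samples, tie-corrected normal approximation otherwise);
the strength-vs-change association is tested with Spearman's rank correlation
and described by an ordinary least-squares line with its R^2.  All p-values
are descriptive.

Pairs farther apart than 19 mm are excluded from statistics: beyond that
distance the treatment light can be undetectable even at normal tissue
absorption (mu_a <= 0.06 mm^-1), which would bias the detectability counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairResult",
    "SpearmanLine",
    "DISTANCE_CUTOFF_MM",
    "results_to_frame",
    "eligibility_filter",
    "mann_whitney_u",
    "spearman_with_line",
    "median_iqr",
    "cohort_summaries",
]

#: Interfiber distance cutoff (mm) for statistical eligibility.
DISTANCE_CUTOFF_MM = 19.0


@dataclass
class PairResult:
    """All per-pair quantities produced by the monitoring pipeline."""

    case_id: str
    pair_id: str
    min_distance_mm: float
    i_t_pre: float = float("nan")
    i_t_post: float = float("nan")
    i_f_pre: float = float("nan")
    i_f_post: float = float("nan")
    trans_detectable_pre: bool = False
    trans_detectable_post: bool = False
    fluor_detectable_pre: bool = False
    fluor_detectable_post: bool = False
    ratio: float = float("nan")
    ratio_qualifier: str = ""
    mu_a_pre: float = float("nan")
    mu_a_pre_qualifier: str = ""
    mu_a_post: float = float("nan")
    mu_a_post_qualifier: str = ""
    delta_mu_a: float = float("nan")
    delta_qualifier: str = ""
    hyper_involved: bool = False
    overlap_fraction: float = 0.0
    strength: float = 0.0
    extras: dict = field(default_factory=dict)


def results_to_frame(results: list[PairResult]) -> pd.DataFrame:
    cols = [f.name for f in fields(PairResult) if f.name != "extras"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def eligibility_filter(
    results: list[PairResult], max_distance_mm: float = DISTANCE_CUTOFF_MM
) -> tuple[list[PairResult], pd.DataFrame]:
    """Retain pairs within the distance cutoff and tabulate detectability counts.

    The counts table mirrors the cohort overview layout: one row for all
    pairs, one for the eligible (<= cutoff) pairs, and the eligible pairs
    split by hyperintensity involvement.  Transmission columns count all pairs
    in the row; fluorescence columns are restricted to pairs with detectable
    pre-iPDT transmission (fluorescence cannot be assessed without excitation
    light reaching the volume) except in the all-pairs row.
    """
    eligible = [r for r in results if r.min_distance_mm <= max_distance_mm]

    def row(subset: list[PairResult], restrict_fluor: bool) -> dict:
        fl = [r for r in subset if r.trans_detectable_pre] if restrict_fluor else subset
        return {
            "n": len(subset),
            "trans_pre_yes": sum(r.trans_detectable_pre for r in subset),
            "trans_pre_no": sum(not r.trans_detectable_pre for r in subset),
            "trans_post_yes": sum(r.trans_detectable_post for r in subset),
            "trans_post_no": sum(not r.trans_detectable_post for r in subset),
            "fluor_pre_yes": sum(r.fluor_detectable_pre for r in fl),
            "fluor_pre_no": sum(not r.fluor_detectable_pre for r in fl),
            "fluor_post_yes": sum(r.fluor_detectable_post for r in fl),
            "fluor_post_no": sum(not r.fluor_detectable_post for r in fl),
        }

    counts = pd.DataFrame(
        {
            "all_distances": row(results, restrict_fluor=False),
            "within_cutoff": row(eligible, restrict_fluor=True),
            "with_hyperintensity": row([r for r in eligible if r.hyper_involved], True),
            "without_hyperintensity": row([r for r in eligible if not r.hyper_involved], True),
        }
    ).T
    return eligible, counts


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is at most 12 and
    holds no ties; otherwise the tie-corrected normal approximation.  If every
    value in both groups is identical the test is vacuous and p = 1 is
    returned with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0.0:
        warnings.warn("all values tied across both groups; p-value is vacuous")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SpearmanLine:
    """Spearman rank test plus a descriptive least-squares line."""

    rho: float
    p_value: float
    r_squared: float
    slope: float
    intercept: float
    n: int


def spearman_with_line(x, y) -> SpearmanLine:
    """Spearman correlation with an OLS line for display.

    The rank correlation carries the inference (two-sided p); the fitted line
    and its R^2 describe the effect on the original scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("rank correlation undefined: a variable has zero variance")
    rho, p = sps.spearmanr(x, y)
    line = sps.linregress(x, y)
    return SpearmanLine(
        rho=float(rho),
        p_value=float(p),
        r_squared=float(line.rvalue**2),
        slope=float(line.slope),
        intercept=float(line.intercept),
        n=int(x.size),
    )


def median_iqr(values) -> tuple[float, float, float]:
    """Median and interquartile range, linear-interpolation quantiles (R-7)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan"), float("nan")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def cohort_summaries(
    overlap_reports: list,
    results: list[PairResult],
    ratio_thresholds: tuple[float, float] = (0.8, 1.2),
) -> tuple[pd.DataFrame, dict]:
    """Medians and IQRs of the cohort-level metrics, plus threshold counts.

    Summarizes the per-case overlap metrics (V_hyp, max diameter, OV, DSC,
    JSC, I_T1) and the per-pair optical quantities (mu_a pre among measured
    values, defined delta mu_a, transmission ratio).  Counts record how many
    pairs crossed the ratio thresholds (default: R < 0.8 for a transmission
    increase beyond the 20% uncertainty, R > 1.2 for a decrease).
    """
    series: dict[str, list] = {}
    if overlap_reports:
        series["v_hyp_mm3"] = [r.v_hyp_mm3 for r in overlap_reports]
        series["max_diameter_mm"] = [
            r.max_diameter_hyp_mm for r in overlap_reports if r.max_diameter_hyp_mm is not None
        ]
        series["ov"] = [r.ov for r in overlap_reports]
        series["dsc"] = [r.dsc for r in overlap_reports]
        series["jsc"] = [r.jsc for r in overlap_reports]
        series["i_t1"] = [r.i_t1 for r in overlap_reports if r.i_t1 is not None]
    if results:
        series["mu_a_pre"] = [
            r.mu_a_pre for r in results if r.mu_a_pre_qualifier == "measured"
        ]
        series["delta_mu_a"] = [
            r.delta_mu_a for r in results if r.delta_qualifier == "measured"
        ]
        series["ratio"] = [r.ratio for r in results if r.ratio_qualifier == "measured"]
    rows = {}
    for name, vals in series.items():
        med, q1, q3 = median_iqr(vals)
        rows[name] = {"n": len(vals), "median": med, "q1": q1, "q3": q3}
    summary = pd.DataFrame(rows).T

    lo, hi = ratio_thresholds
    ratios = np.asarray([r.ratio for r in results if np.isfinite(r.ratio)])
    counts = {
        f"ratio_below_{lo:g}": int((ratios < lo).sum()),
        f"ratio_above_{hi:g}": int((ratios > hi).sum()),
        "n_ratios": int(ratios.size),
    }
    return summary, counts
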