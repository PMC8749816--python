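"""End-to-end per-case analysis: spectra -> optics -> zones -> statistics.

For each ordered fiber pair with a pre and post acquisition the pipeline
extracts the spectral quantities, inverts the per-pair lookup table for the
tissue absorption coefficient before and after the illumination, intersects
the pair's light transmission zone with the hyperintensity label, and feeds
the per-pair results into the cohort statistics.  Every stage is deterministic
given the inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import optics, spectra, stats
from .geometry import CDFPair, build_zone, min_interfiber_distance, zone_overlap
from .io import CaseInputs, RunConfig
from .mri import (
    OverlapReport,
    hyperintensity_strength,
    max_diameter,
    overlap_metrics,
    t1_intensity_norm,
)

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]

log = logging.getLogger("ipdtmon")


@dataclass
class PipelineResult:
    """Bundle of everything one pipeline run produces."""

    pair_results: list
    pair_table: pd.DataFrame
    counts_table: pd.DataFrame
    summary_table: pd.DataFrame
    threshold_counts: dict
    overlap_report: OverlapReport | None = None
    group_comparison: dict = field(default_factory=dict)
    strength_regression: stats.SpearmanLine | None = None


def _index_spectra(spectra_list) -> dict:
    by_pair: dict[tuple, dict] = {}
    for sp in spectra_list:
        key = (str(sp.meta.get("emitter")), str(sp.meta.get("detector")))
        by_pair.setdefault(key, {})[str(sp.meta.get("phase"))] = sp
    return by_pair


def run_pipeline(inputs: CaseInputs, config: RunConfig | None = None) -> PipelineResult:
    """Run the full monitoring analysis for one case."""
    config = config or RunConfig()
    log.info(
        "run start: diffusion point-source model mu_eff = sqrt(3 mu_a (mu_a + mu_s')), "
        "mu_s' = %g mm^-1, zone radius %g mm, cutoff %g mm, detection %gx noise",
        config.mu_s_prime, config.zone_radius_mm,
        config.distance_cutoff_mm, config.detection_multiplier,
    )
    sections = {s.fiber_id: s for s in inputs.sections}
    by_pair = _index_spectra(inputs.spectra)

    has_lesion = inputs.hyper is not None and bool(inputs.hyper.mask.any())
    i_t1 = None
    if inputs.t1 is not None and has_lesion and inputs.wm_spheres:
        i_t1 = t1_intensity_norm(inputs.t1, inputs.hyper, inputs.wm_spheres)

    zone_cache: dict[frozenset, object] = {}
    results = []
    grid = (config.lookup_min, config.lookup_max, config.lookup_step)
    for (em, de), phases in sorted(by_pair.items()):
        if em not in sections or de not in sections:
            raise KeyError(f"stage 'geometry': spectra reference unknown fiber pair {em}->{de}")
        if "pre" not in phases or "post" not in phases:
            log.warning("pair %s->%s lacks a pre or post spectrum; skipped", em, de)
            continue
        pair = CDFPair(sections[em], sections[de])
        res_pre = spectra.assess_spectrum(phases["pre"], inputs.basis, config.detection_multiplier)
        res_post = spectra.assess_spectrum(phases["post"], inputs.basis, config.detection_multiplier)
        ratio, ratio_q = spectra.transmission_ratio(res_pre, res_post)

        table = optics.build_lookup(pair, config.mu_s_prime, config.p0, grid)

        def mua_phase(res: spectra.SpectralResult) -> tuple[float, str]:
            if res.transmission_detectable:
                return optics.invert_mua(res.i_t, table), "measured"
            te = spectra.threshold_equivalent_intensity(res.noise, config.detection_multiplier)
            try:
                return optics.min_mua_for_threshold(te, table), "lower-bound"
            except ValueError:
                return float("nan"), "undetectable"

        mu_pre, q_pre = mua_phase(res_pre)
        mu_post, q_post = mua_phase(res_post)
        dmu, dq = optics.delta_mua(mu_pre, mu_post, q_pre, q_post)

        involved, fraction, strength = False, 0.0, 0.0
        if has_lesion:
            key = frozenset((em, de))
            if key not in zone_cache:
                zone_cache[key] = build_zone(pair, config.zone_radius_mm, config.zone_grid_mm)
            zone = zone_cache[key]
            _, fraction, involved = zone_overlap(zone, inputs.hyper)
            if i_t1 is not None:
                strength = hyperintensity_strength(zone, inputs.hyper, i_t1)

        results.append(
            stats.PairResult(
                case_id=inputs.case_id,
                pair_id=pair.pair_id,
                min_distance_mm=min_interfiber_distance(pair),
                i_t_pre=res_pre.i_t,
                i_t_post=res_post.i_t,
                i_f_pre=res_pre.i_f,
                i_f_post=res_post.i_f,
                trans_detectable_pre=res_pre.transmission_detectable,
                trans_detectable_post=res_post.transmission_detectable,
                fluor_detectable_pre=res_pre.fluorescence_detectable,
                fluor_detectable_post=res_post.fluorescence_detectable,
                ratio=ratio,
                ratio_qualifier=ratio_q,
                mu_a_pre=mu_pre,
                mu_a_pre_qualifier=q_pre,
                mu_a_post=mu_post,
                mu_a_post_qualifier=q_post,
                delta_mu_a=dmu,
                delta_qualifier=dq,
                hyper_involved=involved,
                overlap_fraction=fraction,
                strength=strength,
            )
        )

    eligible, counts = stats.eligibility_filter(results, config.distance_cutoff_mm)

    overlap_report = None
    if inputs.tumor is not None and has_lesion:
        overlap_report = overlap_metrics(inputs.tumor, inputs.hyper, case_id=inputs.case_id)
        overlap_report.max_diameter_hyp_mm = max_diameter(inputs.hyper)
        overlap_report.i_t1 = i_t1

    summary, thresh_counts = stats.cohort_summaries(
        [overlap_report] if overlap_report else [], eligible
    )

    comparison = {}
    with_h = [r.delta_mu_a for r in eligible if r.hyper_involved and r.delta_qualifier == "measured"]
    without_h = [
        r.delta_mu_a for r in eligible if not r.hyper_involved and r.delta_qualifier == "measured"
    ]
    if with_h and without_h:
        u, p = stats.mann_whitney_u(with_h, without_h)
        comparison["delta_mua_by_hyperintensity"] = {
            "U": u, "p": p, "n_with": len(with_h), "n_without": len(without_h),
        }

    regression = None
    pts = [
        (r.strength, r.delta_mu_a)
        for r in eligible
        if r.delta_qualifier in ("measured", "lower-bound") and np.isfinite(r.delta_mu_a)
    ]
    if len(pts) >= 3:
        x, y = np.array(pts).T
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            regression = stats.spearman_with_line(x, y)

    return PipelineResult(
        pair_results=results,
        pair_table=stats.results_to_frame(results),
        counts_table=counts,
        summary_table=summary,
        threshold_counts=thresh_counts,
        overlap_report=overlap_report,
        group_comparison=comparison,
        strength_regression=regression,
    )


def write_outputs(result: PipelineResult, directory) -> Path:
    """Write the pipeline tables as delimited text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.pair_table.to_csv(directory / "pair_results.tsv", sep="\t", index=False)
    result.counts_table.to_csv(directory / "detectability_counts.tsv", sep="\t")
    result.summary_table.to_csv(directory / "cohort_summary.tsv", sep="\t")
    lines = [f"{k}\t{v}" for k, v in result.threshold_counts.items()]
    if result.overlap_report is not None:
        rep = result.overlap_report
        for name in (
            "v_t_mm3", "v_hyp_mm3", "intersection_mm3", "dsc", "jsc", "ov",
            "vhyp_over_vt_percent", "intersection_over_vt", "max_diameter_hyp_mm", "i_t1",
        ):
            lines.append(f"overlap_{name}\t{getattr(rep, name)}")
    for name, stats_dict in result.group_comparison.items():
        for k, v in stats_dict.items():
            lines.append(f"{name}_{k}\t{v}")
    if result.strength_regression is not None:
        reg = result.strength_regression
        for k in ("rho", "p_value", "r_squared", "slope", "intercept", "n"):
            lines.append(f"strength_regression_{k}\t{getattr(reg, k)}")
    (directory / "run_report.tsv").write_text("\n".join(lines) + "\n")
    return directory
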