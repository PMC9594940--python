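"""End-to-end study pipeline: validate -> score -> respond -> biomarkers
-> agreement -> survival, collected into one serialisable report.

The per-case reference score used for the score-vs-response cross-
tabulation and the score-based survival grouping is the median of the
rater scores (integral for an odd rater count). Percentages are
rendered to one decimal and kappa to two, matching the reporting
conventions of the underlying study design.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from irhpc import biomarkers as bm
from irhpc import response as resp
from irhpc import scoring
from irhpc import stats as st
from irhpc import survival as surv
from irhpc.cohort_model import (
    CohortError,
    pdl1_records_from_frame,
    read_cohort,
    records_from_frame,
)

__version__ = "0.1.0"


@dataclass
class StudyReport:
    """Structured results of one full study run (JSON-serialisable)."""

    cohort: dict = field(default_factory=dict)        # sizes in/out per stage
    response: dict = field(default_factory=dict)      # %RVT, classes, MPR rate
    scores: dict = field(default_factory=dict)        # per-rater + reference scores
    score_vs_response: dict = field(default_factory=dict)
    agreement: dict = field(default_factory=dict)     # OPA + kappa at the cutoff
    necrosis: dict = field(default_factory=dict)      # with/without comparison
    immune_activated: dict = field(default_factory=dict)
    dnlr: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)      # KM rates per grouping
    pdl1: dict = field(default_factory=dict)          # eosinophil x TPS tables
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(**d)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def run_study(patients_path: str | Path, pdl1_path: str | Path | None = None,
              config: dict | None = None) -> StudyReport:
    """Run the complete analysis on cohort tables.

    ``config`` keys (all optional): ``cutoff`` (score cutoff, default
    2), ``dnlr_threshold`` (default 3), ``min_pdl1_cells`` (default
    100), ``include_necrosis`` (default True). Aborts with CohortError
    when validation fails.
    """
    config = dict(config or {})
    cutoff = int(config.get("cutoff", scoring.DEFAULT_CUTOFF))
    dnlr_thr = float(config.get("dnlr_threshold", bm.DNLR_THRESHOLD))
    min_cells = int(config.get("min_pdl1_cells", bm.MIN_VIABLE_CELLS))
    include_necrosis = bool(config.get("include_necrosis", True))

    frame, violations = read_cohort(patients_path, "patients")
    if violations:
        raise CohortError("patients table failed validation: "
                          + "; ".join(str(v) for v in violations))
    records = records_from_frame(frame)
    if not records:
        raise CohortError("empty patients cohort")
    report = StudyReport()
    report.meta = {"version": __version__, "config": {
        "cutoff": cutoff, "dnlr_threshold": dnlr_thr,
        "min_pdl1_cells": min_cells, "include_necrosis": include_necrosis}}
    report.cohort["n_enrolled"] = len(records)

    # ---- pathologic response on the cross-rater mean %RVT -----------------
    classes: dict[str, str] = {}
    mean_pct: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in records:
            if not rec.areas:
                continue
            pct = resp.mean_rvt_across_raters(
                [resp.percent_rvt(a, include_necrosis=include_necrosis)
                 for a in rec.areas.values()])
            mean_pct[rec.case_id] = pct
            classes[rec.case_id] = resp.classify_response(pct).value
    n_eval = len(classes)
    n_mpr = sum(resp.mpr_achieved(c) for c in classes.values())
    report.response = {
        "n_evaluable": n_eval,
        "mean_rvt_percent": {k: round(v, 1) for k, v in mean_pct.items()},
        "response_class": classes,
        "n_mpr_achieved": n_mpr,
        "mpr_rate_percent": round(100.0 * n_mpr / n_eval, 1) if n_eval else None,
        "class_counts": {c: sum(1 for v in classes.values() if v == c)
                         for c in ("cPR", "MPR", "pPR", "nPR")},
    }

    # ---- irHPC scores ------------------------------------------------------
    per_rater: dict[str, dict[str, int]] = {}
    reference: dict[str, int] = {}
    for rec in records:
        if not rec.grades:
            continue
        per_rater[rec.case_id] = {
            r: scoring.irhpc_score(g, cutoff=cutoff).value for r, g in rec.grades.items()}
        reference[rec.case_id] = int(np.median(list(per_rater[rec.case_id].values())))
    report.scores = {
        "cutoff": cutoff,
        "per_rater": per_rater,
        "reference": reference,
        "predicted_responder": {c: s >= cutoff for c, s in reference.items()},
    }

    # ---- score vs actual response at the cutoff ---------------------------
    paired = {c: s for c, s in reference.items() if c in classes}
    if paired:
        summary = scoring.score_group_summary(
            paired, {c: classes[c] for c in paired}, cutoff=cutoff)
        report.score_vs_response = {
            g: {"n": s.n, "n_at_or_above_cutoff": s.n_at_or_above_cutoff,
                "percent_at_or_above": s.percent_at_or_above, "undefined": s.undefined}
            for g, s in summary.items()}

    # ---- inter-rater agreement on the binary prediction --------------------
    rated = [c for c, d in per_rater.items() if len(d) >= 2]
    if rated:
        raters = sorted({r for c in rated for r in per_rater[c]})
        mat = np.full((len(rated), len(raters)), np.nan)
        for i, c in enumerate(rated):
            for j, r in enumerate(raters):
                if r in per_rater[c]:
                    mat[i, j] = 1.0 if per_rater[c][r] >= cutoff else 0.0
        agg = st.opa(mat)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kappa, label = st.fleiss_kappa(mat)
        except ValueError:
            kappa, label = None, None
        report.agreement = {
            "n_cases": len(rated), "n_pairs": agg.n_pairs,
            "n_concordant": agg.n_concordant,
            "opa_percent": round(agg.opa, 1),
            "ci95_percent": [round(agg.ci_low, 1), round(agg.ci_high, 1)],
            "kappa": round(kappa, 2) if kappa is not None else None,
            "kappa_label": label,
        }

    # ---- necrosis sensitivity ---------------------------------------------
    with_areas = [r for r in records if r.areas]
    if with_areas:
        ns = resp.necrosis_sensitivity(with_areas)
        report.necrosis = {
            "n_cases": ns.n_cases,
            "n_higher_without": ns.n_higher_without,
            "n_class_changed": ns.n_class_changed,
            "changed_cases": ns.table.loc[ns.table["changed"], "case_id"].tolist(),
            "wilcoxon_p": _jsonable(ns.test.p_value) if ns.test else None,
        }

    # ---- immune-activated %RVT consistency across raters -------------------
    ia_by_rater: dict[str, list[float]] = {}
    for rec in records:
        for r, v in rec.immune_activated_rvt_pct.items():
            ia_by_rater.setdefault(r, []).append(v)
    if len(ia_by_rater) >= 2:
        kw = st.kruskal_wallis(*ia_by_rater.values())
        report.immune_activated = {
            "n_raters": len(ia_by_rater),
            "kruskal_wallis_h": round(kw.statistic, 3),
            "kruskal_wallis_p": _jsonable(kw.p_value),
        }

    # ---- dNLR ---------------------------------------------------------------
    dnlr_flags: dict[str, bool] = {}
    dnlr_values: dict[str, float] = {}
    for rec in records:
        if rec.blood is None:
            continue
        res = bm.dnlr(rec.blood, threshold=dnlr_thr)
        dnlr_values[rec.case_id] = round(res.value, 3)
        dnlr_flags[rec.case_id] = res.high
    report.dnlr = {
        "threshold": dnlr_thr,
        "n_with_counts": len(dnlr_values),
        "n_high": sum(dnlr_flags.values()),
        "values": dnlr_values,
    }

    # ---- survival -----------------------------------------------------------
    analysed, excluded = surv.filter_survival_cohort(records)
    analysed = [r for r in analysed if r.survival is not None]
    report.cohort["n_survival_analysed"] = len(analysed)
    report.cohort["survival_excluded"] = excluded
    if analysed:
        groupings: dict[str, dict[str, str]] = {"all": {r.case_id: "all" for r in analysed}}
        if classes:
            groupings["mpr_achieved"] = {
                r.case_id: ("MPR" if resp.mpr_achieved(classes[r.case_id]) else "non-MPR")
                for r in analysed if r.case_id in classes}
        if reference:
            groupings[f"irhpc_ge_{cutoff}"] = {
                r.case_id: (f"score>={cutoff}" if reference[r.case_id] >= cutoff
                            else f"score<{cutoff}")
                for r in analysed if r.case_id in reference}
        if dnlr_flags:
            groupings["dnlr_gt_3"] = {
                r.case_id: ("dNLR>3" if dnlr_flags[r.case_id] else "dNLR<=3")
                for r in analysed if r.case_id in dnlr_flags}
        surv_out = {}
        for name, mapping in groupings.items():
            subset = [r for r in analysed if r.case_id in mapping]
            if not subset:
                continue
            by_group = surv.km_by_group(subset, mapping)
            surv_out[name] = {
                g: {"n": gs.n,
                    "dfs_1yr": round(100 * gs.dfs_1yr, 1),
                    "dfs_2yr": round(100 * gs.dfs_2yr, 1),
                    "os_1yr": round(100 * gs.os_1yr, 1),
                    "os_2yr": round(100 * gs.os_2yr, 1)}
                for g, gs in by_group.items()}
        med_dfs, rng_dfs = surv.median_followup([r.survival.dfs_time for r in analysed])
        med_os, rng_os = surv.median_followup([r.survival.os_time for r in analysed])
        report.survival = {
            "groupings": surv_out,
            "median_followup_dfs": [round(med_dfs, 1), round(rng_dfs[0], 1),
                                    round(rng_dfs[1], 1)],
            "median_followup_os": [round(med_os, 1), round(rng_os[0], 1),
                                   round(rng_os[1], 1)],
        }

    # ---- PD-L1 series --------------------------------------------------------
    if pdl1_path is not None:
        pframe, pviol = read_cohort(pdl1_path, "pdl1")
        if pviol:
            raise CohortError("pdl1 table failed validation: "
                              + "; ".join(str(v) for v in pviol))
        precs = pdl1_records_from_frame(pframe)
        kept, log = bm.filter_pdl1_evaluable(precs, min_cells=min_cells)
        tables = {}
        for cut in (50, 1):
            try:
                tab = bm.eosinophil_pdl1_table(kept, tps_cutoff=cut)
                tables[str(cut)] = {
                    "cells": [list(r) for r in tab.cells],
                    "chi2": round(tab.test.statistic, 3),
                    "p": _jsonable(tab.test.p_value),
                    "degenerate": tab.test.degenerate,
                }
            except ValueError:
                tables[str(cut)] = None
        report.pdl1 = {
            "n_records": len(precs),
            "n_evaluable": len(kept),
            "excluded": [{"case_id": e.case_id, "reason": e.reason} for e in log],
            "eos_tps_tables": tables,
        }
        report.cohort["n_pdl1_evaluable"] = len(kept)
    return report


def render_report(report: StudyReport, path: str | Path, fmt: str = "json") -> None:
    """Write a report as round-trippable JSON or a readable text summary."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1, default=_jsonable),
                        encoding="utf-8")
    elif fmt == "text":
        path.write_text(_render_text(report), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _render_text(report: StudyReport) -> str:
    d = report.to_dict()
    lines = ["Study report", "============", ""]
    lines.append(f"Enrolled patients: {d['cohort'].get('n_enrolled')}")
    if d["response"]:
        lines.append(f"MPR achieved: {d['response']['n_mpr_achieved']}/"
                     f"{d['response']['n_evaluable']} "
                     f"({d['response']['mpr_rate_percent']}%)")
        lines.append("Response classes: " + ", ".join(
            f"{k}={v}" for k, v in d["response"]["class_counts"].items()))
    if d["score_vs_response"]:
        for g, s in d["score_vs_response"].items():
            lines.append(f"Scores >= cutoff in {g}: {s['n_at_or_above_cutoff']}/{s['n']} "
                         f"({s['percent_at_or_above']}%)")
    if d["agreement"]:
        a = d["agreement"]
        lines.append(f"OPA: {a['opa_percent']}% ({a['n_concordant']}/{a['n_pairs']} pairs; "
                     f"95% CI {a['ci95_percent'][0]}-{a['ci95_percent'][1]})")
        if a["kappa"] is not None:
            lines.append(f"Fleiss kappa: {a['kappa']} ({a['kappa_label']})")
    if d["necrosis"]:
        n = d["necrosis"]
        lines.append(f"Necrosis sensitivity: %RVT higher without necrosis in "
                     f"{n['n_higher_without']}/{n['n_cases']} cases; "
                     f"class changed in {n['n_class_changed']}")
    if d["dnlr"]:
        lines.append(f"dNLR > {d['dnlr']['threshold']}: {d['dnlr']['n_high']}/"
                     f"{d['dnlr']['n_with_counts']}")
    if d["survival"]:
        for name, groups in d["survival"]["groupings"].items():
            for g, r in groups.items():
                lines.append(f"KM [{name}] {g} (n={r['n']}): DFS 1/2yr "
                             f"{r['dfs_1yr']}%/{r['dfs_2yr']}%, OS 1/2yr "
                             f"{r['os_1yr']}%/{r['os_2yr']}%")
    if d["pdl1"]:
        lines.append(f"PD-L1 evaluable: {d['pdl1']['n_evaluable']}/{d['pdl1']['n_records']}")
        for cut, tab in d["pdl1"]["eos_tps_tables"].items():
            if tab:
                lines.append(f"Eos x TPS>={cut}: cells={tab['cells']} p={tab['p']:.3g}")
    return "\n".join(lines) + "\n"
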