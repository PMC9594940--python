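"""%RVT computation and pathologic-response classification.

The per cent of residual viable tumour is viable tumour area over the
total tumour bed (RVT + necrosis + regression bed); the without-necrosis
variant drops necrosis from the denominator, so it is always at least as
large. Response classes partition [0, 100] as cPR = {0},
MPR = (0, 10], pPR = (10, 90], nPR = (90, 100]; "MPR achieved" pools
cPR and MPR. Classification uses the cross-rater mean percent, with
per-rater classes also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from irhpc.cohort_model import PatientRecord, TumourBedAreas
from irhpc.stats import WilcoxonResult, wilcoxon_signed_rank


class ResponseClass(str, Enum):
    cPR = "cPR"
    MPR = "MPR"
    pPR = "pPR"
    nPR = "nPR"


def percent_rvt(areas: TumourBedAreas, include_necrosis: bool = True) -> float:
    """Per cent residual viable tumour for one case.

    With necrosis: 100 * rvt / (rvt + necrosis + regression).
    Without: 100 * rvt / (rvt + regression). No rounding is applied
    before classification; round only for display.
    """
    problems = areas.validate()
    if problems:
        raise ValueError("invalid areas: " + "; ".join(map(str, problems)))
    denom = areas.tumour_bed if include_necrosis else areas.rvt_area + areas.regression_area
    if denom <= 0:
        raise ZeroDivisionError(
            "tumour bed reduces to necrosis only; %RVT-without-necrosis is undefined "
            f"(rvt={areas.rvt_area}, regression={areas.regression_area})")
    return 100.0 * areas.rvt_area / denom


def classify_response(rvt_percent: float) -> ResponseClass:
    """Map a %RVT value to its response class (cPR/MPR/pPR/nPR)."""
    if not (0 <= rvt_percent <= 100):
        raise ValueError(f"%RVT must lie in [0,100], got {rvt_percent!r}")
    if rvt_percent == 0:
        return ResponseClass.cPR
    if rvt_percent <= 10:
        return ResponseClass.MPR
    if rvt_percent <= 90:
        return ResponseClass.pPR
    return ResponseClass.nPR


def mpr_achieved(response: ResponseClass | str) -> bool:
    """True for cPR and MPR: complete responses count as achieving MPR."""
    return ResponseClass(response) in (ResponseClass.cPR, ResponseClass.MPR)


def mean_rvt_across_raters(percents) -> float:
    """Arithmetic mean of per-rater %RVT values, skipping missing raters.

    A single contributing rater triggers a warning; no contributing
    rater is an error.
    """
    vals = [v for v in percents if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no non-missing rater %RVT values")
    if len(vals) < len(list(percents)):
        warnings.warn("missing rater %RVT values excluded from the mean", stacklevel=2)
    if len(vals) == 1:
        warnings.warn("single rater: mean %RVT equals that rater's value", stacklevel=2)
    return float(np.mean(vals))


@dataclass
class NecrosisSensitivity:
    """Per-case comparison of the two %RVT formulas across a cohort."""

    table: pd.DataFrame            # case_id, pct_with, pct_without, class_with, class_without, changed
    n_cases: int
    n_higher_without: int          # cases where dropping necrosis raises %RVT
    n_class_changed: int
    test: WilcoxonResult | None    # paired signed-rank on (without - with); None if degenerate


def _case_mean_percents(rec: PatientRecord, include_necrosis: bool) -> float:
    return mean_rvt_across_raters(
        [percent_rvt(a, include_necrosis=include_necrosis) for a in rec.areas.values()])


def necrosis_sensitivity(records: list[PatientRecord]) -> NecrosisSensitivity:
    """Compare with- vs without-necrosis %RVT case by case.

    Uses the cross-rater mean percent per case, flags response-class
    changes, and runs the Wilcoxon signed-rank test on the paired
    differences (degenerate when all differences are zero).
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in records:
            if not rec.areas:
                continue
            pw = _case_mean_percents(rec, include_necrosis=True)
            pwo = _case_mean_percents(rec, include_necrosis=False)
            cw, cwo = classify_response(pw), classify_response(pwo)
            rows.append({"case_id": rec.case_id, "pct_with": pw, "pct_without": pwo,
                         "class_with": cw.value, "class_without": cwo.value,
                         "changed": cw != cwo})
    if not rows:
        raise ValueError("no cases with tumour-bed areas")
    table = pd.DataFrame(rows)
    diffs = table["pct_without"] - table["pct_with"]
    test = None
    if (diffs != 0).any():
        test = wilcoxon_signed_rank(table["pct_without"].to_numpy(),
                                    table["pct_with"].to_numpy())
    return NecrosisSensitivity(
        table=table,
        n_cases=len(table),
        n_higher_without=int((diffs > 0).sum()),
        n_class_changed=int(table["changed"].sum()),
        test=test,
    )
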