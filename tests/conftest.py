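"""Shared fixtures: a paper-shaped 31-patient cohort built
programmatically, plus the matching PD-L1 series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irhpc.cohort_model import PATIENT_COLUMNS, PDL1_COLUMNS

# Grade quadruples (til, eos, neut, plasma) with known scores.
HIGH = (2, 1, 0, 0)    # score 3  -> predicted responder
LOW = (1, 0, 1, 0)     # score 0  -> predicted non-responder
MID = (1, 0, 0, 0)     # score 1  -> predicted non-responder


def _patient_rows(case_id, grade_triple, areas, blood, survival):
    """Three rater rows for one case. grade_triple: per-rater grade
    quadruples or (None, None, None) for cases without a biopsy."""
    rows = []
    for j, rater in enumerate(("R1", "R2", "R3")):
        g = grade_triple[j] if grade_triple else None
        rows.append({
            "case_id": case_id, "rater_id": rater,
            "til_grade": g[0] if g else None, "eos_grade": g[1] if g else None,
            "neut_grade": g[2] if g else None, "dense_plasma": g[3] if g else None,
            "rvt_area": areas[0], "necrosis_area": areas[1], "regression_area": areas[2],
            "immune_activated_rvt_pct": 100.0 if areas[0] > 0 else None,
            "neutrophil_count": blood[0], "leukocyte_count": blood[1],
            "dfs_months": survival[0], "dfs_event": survival[1],
            "os_months": survival[2], "os_event": survival[3],
            "death_unrelated": survival[4],
        })
    return rows


def build_study_cohort() -> pd.DataFrame:
    """31 neoadjuvant cases, 3 raters, shaped like the published series.

    Response classes by cross-rater mean %RVT: 6 cPR + 9 MPR (15/31 =
    48.4% achieve MPR), 14 pPR, 2 nPR. Cases C01..C15 carry biopsy
    grades arranged so that, at the 2-point cutoff, the 15x3 binary
    rating matrix has 10 unanimous rows and 5 rows split 2-vs-1 (35/45
    concordant pairs, OPA 77.8%), the median reference score is >= 2
    for 7 of the 8 cPR/MPR biopsy cases (C13 scores 0) and < 2 for all
    7 pPR/nPR biopsy cases. Case C14 has tumour-bed areas (10, 60, 30):
    10% RVT with necrosis, 25% without. Ten cases have dNLR > 3; two
    deaths are flagged unrelated to treatment.
    """
    uh = (HIGH, HIGH, HIGH)            # unanimous high: scores 3,3,3
    ul = (LOW, LOW, LOW)               # unanimous low: 0,0,0
    sh = (MID, HIGH, HIGH)             # split, median 3 -> responder
    sl = (HIGH, MID, MID)              # split, median 1 -> non-responder
    # biopsy grade layout for C01..C15
    grades = {
        # cPR/MPR biopsy cases: C01..C06 (cPR), C13, C14 (MPR)
        "C01": uh, "C02": uh, "C03": uh, "C04": uh, "C05": uh, "C06": sh,
        "C13": ul,            # the one low-scoring responder
        "C14": uh,
        # pPR/nPR biopsy cases: C07..C12, C15
        "C07": ul, "C08": ul, "C09": sl, "C10": sl, "C11": sl, "C12": sl,
        "C15": (MID, MID, MID),
    }
    # areas (rvt, necrosis, regression); tumour bed 100 throughout
    areas = {}
    for i in range(1, 7):              # C01..C06: cPR
        areas[f"C{i:02d}"] = (0.0, 20.0 if i == 1 else 0.0, 80.0 if i == 1 else 100.0)
    mpr_ids = ["C13", "C14", "C16", "C17", "C18", "C19", "C20", "C21", "C22"]
    for k, cid in enumerate(mpr_ids):  # 9 MPR cases
        areas[cid] = (10.0, 60.0, 30.0) if cid == "C14" else (4.0 + k * 0.4, 10.0, 86.0 - k * 0.4)
    ppr_ids = ["C07", "C08", "C09", "C10", "C11", "C12", "C15"] + \
              [f"C{i}" for i in range(23, 30)]
    for k, cid in enumerate(ppr_ids):  # 14 pPR cases
        areas[cid] = (30.0 + 3 * k, 5.0, 65.0 - 3 * k)
    areas["C30"] = (95.0, 0.0, 5.0)    # 2 nPR cases
    areas["C31"] = (92.0, 3.0, 5.0)
    rows = []
    rng = np.random.default_rng(20180307)
    for i in range(1, 32):
        cid = f"C{i:02d}"
        high_dnlr = i in (7, 8, 9, 10, 23, 24, 25, 26, 27, 30)  # 10 cases > 3
        blood = (6.0, 7.5) if high_dnlr else (4.0, 10.0)
        unrelated = i in (28, 29)
        if unrelated:
            survival = (20.0, 1, 20.0, 1, 1)
        elif i in (23, 24):            # treatment-related deaths after relapse
            survival = (15.0, 1, 24.0, 1, 0)
        elif i in (25, 26, 27):        # relapses, alive
            survival = (18.0, 1, float(30 + i), 0, 0)
        else:
            t = float(rng.uniform(19, 45))
            survival = (round(t, 1), 0, round(t + 1.4, 1), 0, 0)
        rows.extend(_patient_rows(cid, grades.get(cid), areas[cid], blood, survival))
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def build_pdl1_series() -> pd.DataFrame:
    """109 biopsies; one with < 100 viable tumour cells. Among the 108
    evaluable: 45 with eosinophils in both compartments (12 TPS >= 50,
    15 in [1,50), 18 < 1) and 63 others (4 / 28 / 31), reproducing the
    published contingency tables at both cutoffs."""
    rows = [{"case_id": "B000", "viable_tumour_cells": 80, "tps_percent": 10.0,
             "eos_both_compartments": 1}]
    spec = [(1, 12, 75.0), (1, 15, 25.0), (1, 18, 0.0),
            (0, 4, 75.0), (0, 28, 25.0), (0, 31, 0.0)]
    k = 1
    for eos, count, tps in spec:
        for _ in range(count):
            rows.append({"case_id": f"B{k:03d}", "viable_tumour_cells": 500,
                         "tps_percent": tps, "eos_both_compartments": eos})
            k += 1
    return pd.DataFrame(rows, columns=PDL1_COLUMNS)


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    return build_study_cohort()


@pytest.fixture(scope="session")
def pdl1_series() -> pd.DataFrame:
    return build_pdl1_series()


@pytest.fixture(scope="session")
def cohort_paths(tmp_path_factory, study_cohort, pdl1_series):
    d = tmp_path_factory.mktemp("cohort")
    patients = d / "patients.csv"
    pdl1 = d / "pdl1.csv"
    study_cohort.to_csv(patients, index=False)
    pdl1_series.to_csv(pdl1, index=False)
    return patients, pdl1
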