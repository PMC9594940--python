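"""Synthetic neoadjuvant cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so
every stage is testable without patient data: latent per-case biopsy
grades observed by several noisy raters, a logistic link from the true
pretreatment score to the probability of achieving MPR, tumour-bed
area compositions producing the target %RVT distribution (with a cPR
point mass and a configurable necrosis fraction), pretreatment blood
counts whose neutrophil fraction tracks the neutrophil grade,
exponential DFS/OS times with administrative censoring, and an
independent PD-L1 series with a configurable eosinophil-to-TPS-high
odds ratio.

Rater noise is a symmetric +/-1 slip on ordinal grades (clipped to
[0,3]) and an independent flip on the binary plasma feature. The
default configuration reproduces the marginal structure of a 31-patient
neoadjuvant series in expectation: ~48% MPR achieved (6 cPR + 9 MPR),
~one third of patients with dNLR > 3, and 45/108 eosinophil-positive
PD-L1 cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from irhpc.cohort_model import PATIENT_COLUMNS, PDL1_COLUMNS


@dataclass(frozen=True)
class ConfusionModel:
    """Rater observation noise.

    With probability ``p_slip`` an ordinal grade slips one step up or
    down (direction symmetric, result clipped to [0,3]); the binary
    plasma call flips with probability ``plasma_flip``.
    """

    p_slip: float = 0.25
    plasma_flip: float = 0.10

    def matrix(self) -> np.ndarray:
        """Row-stochastic 4x4 matrix: P(observed grade | true grade)."""
        if not (0 <= self.p_slip <= 1):
            raise ValueError("p_slip must lie in [0,1]")
        m = np.zeros((4, 4))
        for t in range(4):
            m[t, t] += 1 - self.p_slip
            for step in (-1, 1):
                o = min(3, max(0, t + step))
                m[t, o] += self.p_slip / 2
        return m


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for one simulated cohort. Distances in months,
    blood counts in 10^9/L, areas in arbitrary consistent units."""

    n_patients: int = 31
    n_raters: int = 3
    seed: int = 0
    # latent biopsy feature distributions
    til_probs: tuple = (0.25, 0.35, 0.25, 0.15)
    eos_probs: tuple = (0.45, 0.30, 0.15, 0.10)
    neut_probs: tuple = (0.55, 0.25, 0.12, 0.08)
    plasma_prevalence: float = 0.45
    confusion: ConfusionModel = field(default_factory=ConfusionModel)
    # logistic link: P(MPR achieved) = expit(intercept + slope * true score)
    logit_intercept: float = -1.6
    logit_slope: float = 1.1
    # %RVT mixture: responders split cPR (0%) vs MPR (uniform (0,10]);
    # non-responders uniform (10, 100]
    p_cpr_given_responder: float = 0.4
    necrosis_fraction_mean: float = 0.10
    p_no_necrosis: float = 0.35
    rater_area_sd: float = 0.10          # lognormal sigma on per-rater areas
    tumour_bed_total: float = 100.0
    # blood counts
    leukocyte_mean: float = 7.0
    leukocyte_sd: float = 1.5
    neut_fraction_base: float = 0.66
    neut_fraction_per_grade: float = 0.04
    neut_fraction_sd: float = 0.08
    # survival: exponential hazards per month, administrative censoring
    dfs_hazard_responder: float = 0.002
    dfs_hazard_nonresponder: float = 0.010
    os_hazard_responder: float = 0.0008
    os_hazard_nonresponder: float = 0.004
    censor_horizon: float = 45.0
    p_death_unrelated: float = 0.06
    # PD-L1 series
    n_pdl1: int = 109
    p_insufficient_cells: float = 1.0 / 109.0
    eos_both_prevalence: float = 45.0 / 108.0
    tps_high_prob_noneos: float = 4.0 / 63.0
    eos_tps_high_odds_ratio: float = 5.4
    tps_positive_prob_eos: float = 27.0 / 45.0
    tps_positive_prob_noneos: float = 32.0 / 63.0

    def validate(self) -> list[str]:
        bad = []
        for name in ("til_probs", "eos_probs", "neut_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                bad.append(f"{name}: must be 4 probabilities summing to 1")
        for name in ("plasma_prevalence", "p_cpr_given_responder", "p_no_necrosis",
                     "p_death_unrelated", "p_insufficient_cells", "eos_both_prevalence",
                     "tps_high_prob_noneos", "tps_positive_prob_eos",
                     "tps_positive_prob_noneos"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                bad.append(f"{name}: probability outside [0,1]")
        for name in ("dfs_hazard_responder", "dfs_hazard_nonresponder",
                     "os_hazard_responder", "os_hazard_nonresponder"):
            if getattr(self, name) <= 0:
                bad.append(f"{name}: hazard must be > 0")
        if self.n_patients < 1 or self.n_raters < 1:
            bad.append("n_patients and n_raters must be >= 1")
        return bad


def simulate_raters(true_grades: np.ndarray, confusion: ConfusionModel,
                    n_raters: int, rng: np.random.Generator) -> np.ndarray:
    """Independent per-rater observations of true ordinal grades.

    Returns an (n_cases, n_raters) integer matrix; slips move one step
    with symmetric direction and clip at the 0/3 boundaries.
    """
    true_grades = np.asarray(true_grades, dtype=int)
    m = confusion.matrix()
    out = np.empty((true_grades.size, n_raters), dtype=int)
    for j in range(n_raters):
        u = rng.random(true_grades.size)
        cum = np.cumsum(m[true_grades], axis=1)
        out[:, j] = (u[:, None] > cum).sum(axis=1)
    return out


def expected_opa(confusion_matrix: np.ndarray, true_probs: np.ndarray) -> float:
    """Exact expected pairwise agreement of two independent raters.

    P(agree) = sum_t pi_t * sum_c M[t, c]^2 for confusion matrix M and
    true-category distribution pi.
    """
    m = np.asarray(confusion_matrix, dtype=float)
    pi = np.asarray(true_probs, dtype=float)
    return float(pi @ (m ** 2).sum(axis=1))


def expected_opa_binary_flip(q: float) -> float:
    """Closed form for a binary rating flipped with probability q."""
    return (1 - q) ** 2 + q ** 2


def simulate_survival(is_responder: np.ndarray, hazard_responder: float,
                      hazard_nonresponder: float, censor_horizon: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with administrative censoring.

    Returns (times, events); events are 0 where the exponential draw
    exceeds the censoring horizon.
    """
    lam = np.where(is_responder, hazard_responder, hazard_nonresponder)
    raw = rng.exponential(1.0 / lam)
    events = (raw <= censor_horizon).astype(int)
    times = np.minimum(raw, censor_horizon)
    return times, events


def _draw_tps(rng, p_high, p_pos):
    """TPS percent from band probabilities (high >= 50, positive >= 1)."""
    u = rng.random()
    if u < p_high:
        return float(rng.uniform(50, 100))
    if u < p_pos:
        return float(rng.uniform(1, 50))
    return float(rng.uniform(0, 1))


def simulate_cohort(config: SimulationConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, pdl1, truth) tables for one synthetic cohort.

    The patients and pdl1 frames follow the cohort schemas exactly; the
    truth frame records the latent grades, true score, true response
    class and true hazards per case. Output is deterministic in
    ``config.seed``.
    """
    config = config or SimulationConfig()
    problems = config.validate()
    if problems:
        raise ValueError("invalid simulation config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # latent biopsy features and true score
    til = rng.choice(4, size=n, p=config.til_probs)
    eos = rng.choice(4, size=n, p=config.eos_probs)
    neut = rng.choice(4, size=n, p=config.neut_probs)
    plasma = (rng.random(n) < config.plasma_prevalence).astype(int)
    true_score = til + eos - neut + plasma

    # response: logistic in the true score, then the %RVT mixture
    p_mpr = 1.0 / (1.0 + np.exp(-(config.logit_intercept + config.logit_slope * true_score)))
    responder = rng.random(n) < p_mpr
    rvt_pct = np.empty(n)
    for i in range(n):
        if responder[i]:
            rvt_pct[i] = 0.0 if rng.random() < config.p_cpr_given_responder \
                else rng.uniform(1e-6, 10.0)
        else:
            rvt_pct[i] = rng.uniform(10.0 + 1e-6, 100.0)
    true_class = np.where(rvt_pct == 0, "cPR",
                  np.where(rvt_pct <= 10, "MPR",
                   np.where(rvt_pct <= 90, "pPR", "nPR")))

    # tumour-bed composition: fixed total bed, necrosis as a fraction of
    # the non-viable remainder (zero for a share of cases)
    bed = config.tumour_bed_total
    rvt_area = bed * rvt_pct / 100.0
    nonviable = bed - rvt_area
    necro_frac = rng.beta(2, 2 / max(config.necrosis_fraction_mean, 1e-6) - 2, size=n)
    necro_frac[rng.random(n) < config.p_no_necrosis] = 0.0
    necrosis_area = nonviable * necro_frac
    regression_area = nonviable - necrosis_area

    # blood counts: neutrophil fraction tracks the neutrophil grade
    leuko = np.maximum(rng.normal(config.leukocyte_mean, config.leukocyte_sd, n), 3.0)
    frac = np.clip(rng.normal(config.neut_fraction_base
                              + config.neut_fraction_per_grade * neut,
                              config.neut_fraction_sd), 0.20, 0.92)
    neut_count = leuko * frac

    # survival per response group; a few deaths unrelated to treatment
    os_t, os_e = simulate_survival(responder, config.os_hazard_responder,
                                   config.os_hazard_nonresponder,
                                   config.censor_horizon, rng)
    dfs_t, dfs_e = simulate_survival(responder, config.dfs_hazard_responder,
                                     config.dfs_hazard_nonresponder,
                                     config.censor_horizon, rng)
    dfs_t = np.minimum(dfs_t, os_t)
    dfs_e = np.where((os_e == 1) & (os_t <= dfs_t), 1, dfs_e)
    unrelated = ((rng.random(n) < config.p_death_unrelated) & (os_e == 1)).astype(int)

    # per-rater observations
    raters = [f"R{j + 1}" for j in range(config.n_raters)]
    til_obs = simulate_raters(til, config.confusion, config.n_raters, rng)
    eos_obs = simulate_raters(eos, config.confusion, config.n_raters, rng)
    neut_obs = simulate_raters(neut, config.confusion, config.n_raters, rng)
    plasma_obs = np.where(rng.random((n, config.n_raters)) < config.confusion.plasma_flip,
                          1 - plasma[:, None], plasma[:, None])
    area_noise = rng.lognormal(0.0, config.rater_area_sd, size=(n, config.n_raters, 3))
    # immune-activated share of RVT: mostly 100% where residual tumour exists
    ia_true = np.where(rvt_pct == 0, np.nan,
                       np.where(rng.random(n) < 0.8, 100.0, rng.uniform(60, 100, n)))
    ia_obs = np.clip(ia_true[:, None] + rng.normal(0, 3.0, (n, config.n_raters)), 0, 100)

    rows = []
    for i in range(n):
        cid = f"P{i + 1:03d}"
        for j, rater in enumerate(raters):
            rows.append({
                "case_id": cid, "rater_id": rater,
                "til_grade": int(til_obs[i, j]), "eos_grade": int(eos_obs[i, j]),
                "neut_grade": int(neut_obs[i, j]), "dense_plasma": int(plasma_obs[i, j]),
                "rvt_area": round(rvt_area[i] * area_noise[i, j, 0], 4),
                "necrosis_area": round(necrosis_area[i] * area_noise[i, j, 1], 4),
                "regression_area": round(regression_area[i] * area_noise[i, j, 2], 4),
                "immune_activated_rvt_pct": (round(float(ia_obs[i, j]), 2)
                                             if np.isfinite(ia_obs[i, j]) else None),
                "neutrophil_count": round(float(neut_count[i]), 3),
                "leukocyte_count": round(float(leuko[i]), 3),
                "dfs_months": round(float(dfs_t[i]), 3), "dfs_event": int(dfs_e[i]),
                "os_months": round(float(os_t[i]), 3), "os_event": int(os_e[i]),
                "death_unrelated": int(unrelated[i]),
            })
    patients = pd.DataFrame(rows, columns=PATIENT_COLUMNS)

    # PD-L1 series (independent of the neoadjuvant cohort)
    odds_no = config.tps_high_prob_noneos / (1 - config.tps_high_prob_noneos)
    odds_eos = odds_no * config.eos_tps_high_odds_ratio
    p_high_eos = odds_eos / (1 + odds_eos)
    pdl1_rows = []
    for i in range(config.n_pdl1):
        eos_both = rng.random() < config.eos_both_prevalence
        cells = (int(rng.integers(20, 100)) if rng.random() < config.p_insufficient_cells
                 else int(rng.integers(100, 5000)))
        if eos_both:
            tps = _draw_tps(rng, p_high_eos, config.tps_positive_prob_eos)
        else:
            tps = _draw_tps(rng, config.tps_high_prob_noneos, config.tps_positive_prob_noneos)
        pdl1_rows.append({"case_id": f"B{i + 1:03d}", "viable_tumour_cells": cells,
                          "tps_percent": round(tps, 2),
                          "eos_both_compartments": int(eos_both)})
    pdl1 = pd.DataFrame(pdl1_rows, columns=PDL1_COLUMNS)

    truth = pd.DataFrame({
        "case_id": [f"P{i + 1:03d}" for i in range(n)],
        "true_til": til, "true_eos": eos, "true_neut": neut, "true_plasma": plasma,
        "true_score": true_score, "responder": responder.astype(int),
        "true_rvt_pct": rvt_pct, "true_class": true_class,
        "dfs_hazard": np.where(responder, config.dfs_hazard_responder,
                               config.dfs_hazard_nonresponder),
        "os_hazard": np.where(responder, config.os_hazard_responder,
                              config.os_hazard_nonresponder),
    })
    return patients, pdl1, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "confusion" in d and isinstance(d["confusion"], dict):
        d["confusion"] = ConfusionModel(**d["confusion"])
    for k in ("til_probs", "eos_probs", "neut_probs"):
        if k in d:
            d[k] = tuple(d[k])
    return SimulationConfig(**d)
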