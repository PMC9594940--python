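"""Synthetic cohort generator: determinism, schema conformance and
statistical recovery against closed forms."""

import numpy as np
import pandas as pd
import pytest

from irhpc.cohort_model import read_cohort, records_from_frame
from irhpc.simulate import (
    ConfusionModel,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    expected_opa,
    expected_opa_binary_flip,
    simulate_cohort,
    simulate_raters,
    simulate_survival,
)
from irhpc.stats import opa


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1))[0]
        b = simulate_cohort(SimulationConfig(seed=2))[0]
        assert not a.equals(b)

    def test_config_round_trip(self):
        cfg = SimulationConfig(seed=7, n_patients=12,
                               confusion=ConfusionModel(p_slip=0.4))
        assert config_from_dict(config_to_dict(cfg)) == cfg


class TestSchemaConformance:
    def test_default_cohort_passes_validation(self, tmp_path):
        patients, pdl1, truth = simulate_cohort(SimulationConfig(seed=3))
        pp, dp = tmp_path / "p.csv", tmp_path / "d.csv"
        patients.to_csv(pp, index=False)
        pdl1.to_csv(dp, index=False)
        _, v1 = read_cohort(pp, "patients")
        _, v2 = read_cohort(dp, "pdl1")
        assert v1 == [] and v2 == []
        assert len(truth) == 31
        assert len(records_from_frame(patients)) == 31

    def test_truth_table_consistency(self):
        _, _, truth = simulate_cohort(SimulationConfig(seed=4))
        score = (truth.true_til + truth.true_eos - truth.true_neut + truth.true_plasma)
        assert (score == truth.true_score).all()
        assert set(truth.true_class) <= {"cPR", "MPR", "pPR", "nPR"}
        # response class consistent with the latent %RVT
        assert ((truth.true_rvt_pct == 0) == (truth.true_class == "cPR")).all()

    def test_invalid_config_names_fields(self):
        bad = SimulationConfig(plasma_prevalence=1.5, dfs_hazard_responder=-1)
        with pytest.raises(ValueError, match="plasma_prevalence"):
            simulate_cohort(bad)


class TestRaterNoise:
    def test_zero_slip_reproduces_truth(self):
        rng = np.random.default_rng(0)
        truth = np.array([0, 1, 2, 3, 2, 1])
        obs = simulate_raters(truth, ConfusionModel(p_slip=0.0), 3, rng)
        assert (obs == truth[:, None]).all()

    def test_forced_slip_never_matches_interior_truth(self):
        rng = np.random.default_rng(1)
        truth = np.full(500, 2)
        obs = simulate_raters(truth, ConfusionModel(p_slip=1.0), 2, rng)
        assert not (obs == 2).any()
        assert set(np.unique(obs)) <= {1, 3}

    def test_identity_model_gives_perfect_downstream_opa(self):
        cfg = SimulationConfig(seed=5, confusion=ConfusionModel(p_slip=0.0,
                                                                plasma_flip=0.0))
        patients, _, _ = simulate_cohort(cfg)
        wide = patients.pivot(index="case_id", columns="rater_id", values="til_grade")
        assert opa(wide.to_numpy(dtype=float)).opa == 100.0

    def test_confusion_matrix_rows_stochastic(self):
        m = ConfusionModel(p_slip=0.3).matrix()
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        assert m[0, 0] == pytest.approx(0.85)  # boundary clip folds back
        assert m[1, 1] == pytest.approx(0.70)


class TestExpectedOpa:
    def test_identity_model(self):
        assert expected_opa(np.eye(4), [0.25] * 4) == 1.0

    @pytest.mark.parametrize("q, expected", [(0.5, 0.5), (0.1, 0.82), (0.0, 1.0)])
    def test_binary_flip_closed_form(self, q, expected):
        m = np.array([[1 - q, q], [q, 1 - q]])
        assert expected_opa(m, [0.5, 0.5]) == pytest.approx(expected)
        assert expected_opa_binary_flip(q) == pytest.approx(expected)

    def test_monte_carlo_agreement_at_1e4(self):
        """Empirical pairwise agreement of two flipped binary raters
        converges to (1-q)^2 + q^2 within 3 MC standard errors."""
        q, n = 0.1, 10_000
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 2, n)
        flips = rng.random((n, 2)) < q
        obs = np.where(flips, 1 - truth[:, None], truth[:, None])
        emp = opa(obs.astype(float)).opa / 100
        exp = expected_opa_binary_flip(q)
        se = np.sqrt(exp * (1 - exp) / n)
        assert abs(emp - exp) < 3 * se

    def test_ordinal_confusion_monte_carlo(self):
        """The general category-pair sum matches simulated raters."""
        cm = ConfusionModel(p_slip=0.3)
        probs = np.array([0.2, 0.3, 0.3, 0.2])
        exp = expected_opa(cm.matrix(), probs)
        rng = np.random.default_rng(7)
        truth = rng.choice(4, 10_000, p=probs)
        obs = simulate_raters(truth, cm, 2, rng)
        emp = float((obs[:, 0] == obs[:, 1]).mean())
        se = np.sqrt(exp * (1 - exp) / 10_000)
        assert abs(emp - exp) < 3 * se


class TestSurvivalGenerator:
    def test_tiny_hazard_all_censored(self):
        rng = np.random.default_rng(8)
        t, e = simulate_survival(np.ones(50, bool), 1e-9, 1e-9, 45.0, rng)
        assert (e == 0).all() and (t == 45.0).all()

    def test_closed_form_survival_at_24_months(self):
        """lambda = 0.01/month: S(24) = exp(-0.24) ~ 0.787 at n = 2000."""
        rng = np.random.default_rng(9)
        n = 2000
        t, e = simulate_survival(np.zeros(n, bool), 0.02, 0.01, 45.0, rng)
        emp = float(((t > 24) | ((t == 45.0) & (e == 0))).mean())
        true = np.exp(-0.01 * 24)
        se = np.sqrt(true * (1 - true) / n)
        assert abs(emp - true) < 3 * se

    def test_groups_use_their_own_hazard(self):
        rng = np.random.default_rng(10)
        is_resp = np.repeat([True, False], 3000)
        t, e = simulate_survival(is_resp, 0.001, 0.05, 45.0, rng)
        assert e[~is_resp].mean() > e[is_resp].mean()


class TestEffectRecovery:
    def test_logistic_score_effect_direction_at_n1000(self):
        """The configured positive score -> MPR link is re-estimable in
        sign from the generated truth table."""
        cfg = SimulationConfig(seed=11, n_patients=1000)
        _, _, truth = simulate_cohort(cfg)
        import statsmodels.api as sm
        x = sm.add_constant(truth.true_score.to_numpy(dtype=float))
        fit = sm.Logit(truth.responder.to_numpy(), x).fit(disp=0)
        assert fit.params[1] > 0
        assert fit.pvalues[1] < 0.01

    def test_paper_shaped_marginals_in_expectation(self):
        """Defaults target ~48% MPR achieved and ~1/3 dNLR > 3."""
        cfg = SimulationConfig(seed=12, n_patients=4000)
        patients, _, truth = simulate_cohort(cfg)
        mpr_rate = truth.responder.mean()
        assert 0.35 < mpr_rate < 0.60
        ratio = patients.drop_duplicates("case_id")
        dnlr = ratio.neutrophil_count / (ratio.leukocyte_count - ratio.neutrophil_count)
        assert 0.15 < (dnlr > 3).mean() < 0.50

    def test_eosinophil_tps_association_recovered(self):
        """The configured odds ratio leaves a detectable TPS>=50 excess
        in the eosinophil-both group."""
        cfg = SimulationConfig(seed=13, n_pdl1=3000)
        _, pdl1, _ = simulate_cohort(cfg)
        eos = pdl1[pdl1.eos_both_compartments == 1]
        non = pdl1[pdl1.eos_both_compartments == 0]
        p_eos = (eos.tps_percent >= 50).mean()
        p_non = (non.tps_percent >= 50).mean()
        assert p_eos > 2 * p_non
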