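"""Agreement statistics and nonparametric tests against independent
oracles (brute force, hand computation, closed forms, simulation)."""

import itertools

import numpy as np
import pytest

from irhpc.stats import (
    fleiss_kappa,
    interpret_kappa,
    kruskal_wallis,
    opa,
    opa_from_counts,
    pearson_chi2,
    wilcoxon_signed_rank,
)


def brute_force_opa(matrix):
    """Double loop over cases and rater pairs, the stated oracle."""
    pairs = conc = 0
    for row in np.asarray(matrix, dtype=float):
        present = row[~np.isnan(row)]
        for i, j in itertools.combinations(range(len(present)), 2):
            pairs += 1
            conc += present[i] == present[j]
    return conc, pairs


class TestOpa:
    def test_published_15x3_composition(self):
        """10 unanimous rows plus 5 rows split 2-vs-1 give 35 concordant
        of 45 pairs: OPA 77.8%."""
        matrix = [[1, 1, 1]] * 10 + [[1, 1, 0]] * 5
        res = opa(matrix)
        assert (res.n_concordant, res.n_pairs) == (35, 45)
        assert res.opa == pytest.approx(77.8, abs=0.05)
        assert res.ci_low < res.opa < res.ci_high

    def test_unanimous_and_from_counts(self):
        assert opa([[0, 0, 0]] * 4).opa == 100.0
        assert opa_from_counts(35, 15, 3).opa == pytest.approx(77.8, abs=0.05)
        assert opa_from_counts(45, 15, 3).opa == 100.0
        assert opa_from_counts(0, 15, 3).opa == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = rng.integers(0, 2, size=(20, 3)).astype(float)
            m[rng.random(m.shape) < 0.1] = np.nan
            conc, pairs = brute_force_opa(m)
            if pairs == 0:
                continue
            res = opa(m)
            assert (res.n_concordant, res.n_pairs) == (conc, pairs)
            agg = opa_from_counts(conc, pairs, 2)  # n_pairs = pairs * C(2,2)
            assert agg.opa == pytest.approx(res.opa)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            opa_from_counts(46, 15, 3)

    def test_clopper_pearson_option(self):
        w = opa_from_counts(35, 15, 3, ci_method="wilson")
        cp = opa_from_counts(35, 15, 3, ci_method="clopper-pearson")
        assert cp.ci_low <= w.ci_low and cp.ci_high >= w.ci_high  # CP is conservative


class TestFleissKappa:
    def test_hand_worked_table(self):
        """4 cases x 3 raters, binary. By hand: P_bar = 2/3, category
        proportions 7/12 and 5/12 give P_e = 37/72, kappa = 11/35."""
        m = [[1, 1, 0], [1, 1, 1], [0, 0, 0], [1, 0, 1]]
        kappa, label = fleiss_kappa(m)
        assert kappa == pytest.approx(11 / 35)
        assert label == "poor to fair"

    def test_unanimous_multicategory_is_one(self):
        kappa, label = fleiss_kappa([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        assert kappa == pytest.approx(1.0)
        assert label == "almost perfect"

    def test_null_simulation_near_zero(self):
        """Independent uniform ratings carry no agreement signal."""
        rng = np.random.default_rng(5)
        kappa, _ = fleiss_kappa(rng.integers(0, 4, size=(4000, 3)))
        assert abs(kappa) < 0.03

    def test_single_category_undefined(self):
        with pytest.raises(ValueError, match="single category"):
            fleiss_kappa([[1, 1, 1], [1, 1, 1]])

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        m = rng.integers(0, 3, size=(30, 3))
        k1, _ = fleiss_kappa(m)
        k2, _ = fleiss_kappa(2 - m)  # permute category labels
        assert k1 == pytest.approx(k2)

    def test_unequal_rating_counts_dropped_with_warning(self):
        m = np.array([[1.0, 0, 1], [0, 1, np.nan], [1, 1, 1], [0, 0, 0]])
        with pytest.warns(UserWarning, match="dropping 1"):
            kappa, _ = fleiss_kappa(m)
        ref, _ = fleiss_kappa(np.delete(m, 1, axis=0))
        assert kappa == pytest.approx(ref)


@pytest.mark.parametrize("kappa, label", [
    (0.54, "moderate"),
    (0.40, "poor to fair"),
    (0.404, "poor to fair"),   # band-gap values resolved by 2-decimal rounding
    (0.406, "moderate"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.80, "substantial"),
    (0.81, "almost perfect"),
    (1.0, "almost perfect"),
    (-0.2, "poor to fair"),
])
def test_kappa_interpretation_bands(kappa, label):
    assert interpret_kappa(kappa) == label


class TestWilcoxon:
    def test_17_positive_differences_exact_p(self):
        """All 17 non-zero differences positive: two-sided exact
        p = 2 * (1/2)^17, far below the 0.001 reporting bound."""
        d = np.arange(1.0, 18.0)
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(2 * 0.5 ** 17)
        assert res.n_nonzero == 17

    def test_zeros_dropped(self):
        d = np.concatenate([np.zeros(14), np.arange(1.0, 18.0)])
        res = wilcoxon_signed_rank(d)
        assert res.n_zero_dropped == 14
        assert res.p_value == pytest.approx(2 * 0.5 ** 17)

    def test_all_zero_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(np.zeros(5))

    def test_sign_symmetry(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1, 40)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_signed_rank(-d).p_value)

    def test_paired_form(self):
        x, y = np.array([25.0, 30, 15]), np.array([10.0, 20, 15])
        res = wilcoxon_signed_rank(x, y)
        assert res.n_nonzero == 2 and res.n_zero_dropped == 1


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        """Three groups of three with no ties: H = 7.2 by hand ranks."""
        res = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_identical_groups(self):
        res = kruskal_wallis([1.0, 1, 1], [1.0, 1, 1], [1.0, 1, 1])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_group_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        c = rng.normal(3, 1, 15)
        res = kruskal_wallis(a, b, c)
        # permutation oracle on the H statistic
        from scipy.stats import kruskal
        pooled = np.concatenate([a, b, c])
        h_obs = kruskal(a, b, c).statistic
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += kruskal(perm[:15], perm[15:30], perm[30:]).statistic >= h_obs
        p_perm = (count + 1) / (n_perm + 1)
        assert res.p_value < 0.01 and p_perm < 0.01

    def test_monotone_transformation_invariance(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 12) for m in (0, 0.5, 1)]
        h1 = kruskal_wallis(*groups).statistic
        h2 = kruskal_wallis(*[np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])


class TestPearsonChi2:
    def test_published_tables(self):
        r = pearson_chi2([[12, 33], [4, 59]])
        assert r.statistic == pytest.approx(8.59, abs=0.01)
        assert r.p_value == pytest.approx(0.003, abs=5e-4)
        assert pearson_chi2([[27, 18], [32, 31]]).p_value == pytest.approx(0.343, abs=5e-3)

    def test_hand_formula_oracle(self):
        """chi2 = n(ad - bc)^2 / (r1 r2 c1 c2) on random tables."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, 4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert pearson_chi2([[a, b], [c, d]]).statistic == pytest.approx(expected)

    def test_proportional_table_is_null(self):
        r = pearson_chi2([[10, 20], [20, 40]])
        assert r.statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = [[12, 33], [4, 59]]
        assert pearson_chi2(t).statistic == pytest.approx(
            pearson_chi2(np.transpose(t)).statistic)

    def test_zero_margin_degenerate(self):
        assert pearson_chi2([[0, 0], [4, 59]]).degenerate
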