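import numpy as np
import pingouin
import pandas as pd
import pytest
from scipy import stats as sps

import wordgraphs as wg


class TestSpearman:
    def test_perfect_monotone(self):
        r = wg.spearman([1, 2, 3, 5], [2, 4, 9, 11])
        assert r.statistic == pytest.approx(1.0)

    def test_perfect_antitone(self):
        r = wg.spearman([1, 2, 3, 5], [11, 9, 4, 2])
        assert r.statistic == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # d = (0, 1, -1, 0): rho = 1 - 6*2/(4*15) = 0.8
        r = wg.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.statistic == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            wg.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_variant_agrees(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        approx = wg.spearman(x, y)
        exact = wg.spearman(x, y, exact=True, n_perm=2000, seed=0)
        assert exact.statistic == approx.statistic
        assert exact.p_value == pytest.approx(approx.p_value, abs=0.02)

    def test_significance_flag(self):
        r = wg.spearman(np.arange(20), np.arange(20.0),
                        alpha_corrected=wg.bonferroni(0.05, 8).exact)
        assert r.significant is True


class TestPartialSpearman:
    def test_self_correlation(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        r = wg.partial_spearman(x, x, z)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == 0.0

    def test_constant_covariate_reduces_to_plain(self, rng):
        x, y = rng.normal(size=(2, 25))
        plain = wg.spearman(x, y)
        part = wg.partial_spearman(x, y, np.ones(25))
        assert part.statistic == pytest.approx(plain.statistic)
        assert part.test_name == "partial_spearman"

    def test_independent_covariate_changes_little(self, rng):
        n = 800
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        z = rng.normal(size=n)
        plain = wg.spearman(x, y)
        part = wg.partial_spearman(x, y, z)
        assert part.statistic == pytest.approx(plain.statistic, abs=0.05)

    def test_mediated_association_vanishes(self, rng):
        """y is a monotone function of z; x independent: partial ~ 0."""
        n = 800
        z = rng.normal(size=n)
        y = np.exp(z) + 0.01 * rng.normal(size=n)
        x = rng.normal(size=n)
        part = wg.partial_spearman(x, y, z)
        assert abs(part.statistic) < 0.1

    def test_matches_pingouin_reference(self, rng):
        """Cross-check against an independent implementation of the
        rank-based first-order partial correlation."""
        n = 60
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 0.5 * x + 0.7 * z + rng.normal(size=n)
        ours = wg.partial_spearman(x, y, z)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman")
        assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]),
                                               abs=1e-10)
        assert ours.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                             abs=1e-8)

    def test_collinear_covariate_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            wg.partial_spearman(x, np.arange(10.0)[::-1], x)


class TestMultipleRegression:
    def test_exact_linear_recovery(self, rng):
        age = rng.uniform(5, 50, 40)
        edu = rng.uniform(0, 15, 40)
        res = wg.multiple_regression(2 * edu + 1, age, edu)
        assert res.coef_edu == pytest.approx(2.0)
        assert res.coef_age == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_symmetric_combination(self, rng):
        age = rng.uniform(5, 50, 40)
        edu = rng.uniform(0, 15, 40)
        res = wg.multiple_regression(age + edu, age, edu)
        assert res.coef_diff == pytest.approx(0.0, abs=1e-10)

    def test_independent_outcome_low_r2(self, rng):
        age = rng.uniform(5, 50, 300)
        edu = rng.uniform(0, 15, 300)
        res = wg.multiple_regression(rng.normal(size=300), age, edu)
        assert res.r_squared < 0.05

    def test_singular_design_rejected(self):
        age = np.arange(10.0)
        with pytest.raises(ValueError, match="singular"):
            wg.multiple_regression(np.ones(10), age, 2 * age)


class TestGroupTests:
    def test_corrected_alpha_four_comparisons(self, rng):
        groups = {g: rng.normal(size=12) for g in "abc"}
        res = wg.group_tests(groups, m_corrections=4)
        posthoc = [r for r in res if r.test_name.startswith("wilcoxon")]
        assert all(r.alpha_corrected == pytest.approx(0.0125)
                   for r in posthoc)

    def test_complete_separation(self):
        res = wg.group_tests({"lo": np.arange(10), "hi": np.arange(20, 30)},
                             comparisons=[("lo", "hi")], m_corrections=1)
        w = res[1]
        assert w.statistic == sum(range(1, 11))  # lowest possible rank sum
        assert w.p_value < 0.001

    def test_two_group_kw_wilcoxon_agreement(self, rng):
        """With two large groups the Kruskal-Wallis H equals the squared
        rank-sum z asymptotically, so the p-values agree."""
        a = rng.normal(0, 1, 300)
        b = rng.normal(0.2, 1, 300)
        res = wg.group_tests({"a": a, "b": b})
        kw, w = res[0], res[1]
        assert kw.p_value == pytest.approx(w.p_value, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wg.group_tests({"a": [1.0], "b": [1.0, 2.0]})


class TestDistributionChecks:
    def test_skewed_data_flagged(self, rng):
        skewed = rng.exponential(1.0, 200) ** 2
        res = wg.distribution_checks({"g": skewed})
        ks = res[0]
        assert ks.p_value < 0.01
        assert "approximate" in ks.note

    def test_equal_variance_gaussians_pass_levene(self, rng):
        res = wg.distribution_checks(
            {"a": rng.normal(0, 1, 80), "b": rng.normal(3, 1, 80)})
        levene = res[-1]
        assert levene.p_value > 0.01

    def test_unequal_variance_detected(self, rng):
        res = wg.distribution_checks(
            {"a": rng.normal(0, 1, 120), "b": rng.normal(0, 4, 120)})
        assert res[-1].p_value < 1e-6

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            wg.distribution_checks({"a": [2.0, 2.0, 2.0, 2.0],
                                    "b": [1.0, 2.0, 3.0, 4.0]})


class TestProportionTest:
    def test_identical_proportions(self):
        r = wg.proportion_test(5, 10, 10, 20)
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_hand_computed_extreme_table(self):
        # (10,0 / 0,10): chi2 = 20 without continuity correction
        r = wg.proportion_test(10, 10, 0, 10)
        assert r.statistic == pytest.approx(20.0)

    def test_symmetry(self):
        a = wg.proportion_test(40, 65, 38, 135)
        b = wg.proportion_test(38, 135, 40, 65)
        assert a.statistic == pytest.approx(b.statistic)

    def test_yates_option_shrinks_statistic(self):
        plain = wg.proportion_test(10, 10, 0, 10)
        yates = wg.proportion_test(10, 10, 0, 10, continuity=True)
        assert yates.statistic < plain.statistic

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            wg.proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            wg.proportion_test(11, 10, 1, 10)


class TestBonferroni:
    @pytest.mark.parametrize("alpha, m, exact, reported", [
        (0.05, 8, 0.00625, 0.0063),
        (0.05, 4, 0.0125, 0.0125),
        (0.05, 1, 0.05, 0.05),
        (0.05, 6, 0.05 / 6, 0.0083),
    ])
    def test_correction(self, alpha, m, exact, reported):
        got = wg.bonferroni(alpha, m)
        assert got.exact == pytest.approx(exact)
        assert got.reported == reported

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wg.bonferroni(0.0, 4)
        with pytest.raises(ValueError):
            wg.bonferroni(0.05, 0)


class TestPurity:
    def test_identical_inputs_identical_outputs(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert wg.spearman(x, y) == wg.spearman(x, y)
        assert wg.multiple_regression(y, x, y + x) \
            == wg.multiple_regression(y, x, y + x)
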