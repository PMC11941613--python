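"""Statistical battery: hand-computed oracles, library cross-checks,
degenerate inputs, and the derived effect sizes at printed precision."""

import numpy as np
import pytest
from scipy import stats as sps

from nmjmorph.stats import (
    EffectSizes,
    NestedVarianceProfile,
    chi_square_independence,
    effect_sizes,
    one_way_anova,
    paired_t_test,
    power_check,
    tukey_kramer,
    two_way_anova,
)


class TestOneWayAnova:
    def test_identical_groups_give_zero_F(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic_value == 0.0 and res.p_value == 1.0

    def test_hand_decomposed_example(self):
        # groups {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4 -> F = 13.5
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.statistic_value == pytest.approx(13.5)
        assert res.df_pair == (1, 4)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=60)
        groups = rng.choice(["a", "b", "c"], size=60)
        res = one_way_anova(vals, groups)
        ref = sps.f_oneway(*[vals[groups == g] for g in "abc"])
        assert res.statistic_value == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_ss_decomposition_is_exact(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(1000, 50, size=200)
        groups = rng.choice(["a", "b", "c", "d"], size=200)
        res = one_way_anova(vals, groups)
        total = res.extra["ss_between"] + res.extra["ss_within"]
        assert abs(total - res.extra["ss_total"]) <= 1e-9 * res.extra["ss_total"]

    def test_zero_within_variance_reports_infinite_F(self):
        res = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert np.isinf(res.statistic_value) and res.p_value == 0.0


class TestTwoWayAnova:
    def test_constant_response_gives_zero_F_everywhere(self):
        a = ["x", "x", "y", "y"] * 3
        b = ["u", "v"] * 6
        res = two_way_anova([5.0] * 12, a, b)
        for key in ("factor_a", "factor_b", "interaction"):
            assert res[key].statistic_value == 0.0

    def test_matches_statsmodels_type_ii_on_unbalanced_data(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(3)
        n = 90
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "a": rng.choice(["a1", "a2"], size=n, p=[0.4, 0.6]),
                "b": rng.choice(["b1", "b2", "b3"], size=n),
            }
        )
        df.loc[df.a == "a2", "y"] += 1.0
        mine = two_way_anova(df.y, df.a, df.b)
        table = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
        assert mine["factor_a"].statistic_value == pytest.approx(table.loc["C(a)", "F"])
        assert mine["factor_b"].statistic_value == pytest.approx(table.loc["C(b)", "F"])
        assert mine["interaction"].statistic_value == pytest.approx(
            table.loc["C(a):C(b)", "F"]
        )
        assert mine["interaction"].p_value == pytest.approx(table.loc["C(a):C(b)", "PR(>F)"])

    def test_empty_cell_omits_the_interaction(self):
        a = ["x"] * 4 + ["y"] * 2
        b = ["u", "u", "v", "v", "u", "u"]  # cell (y, v) empty
        with pytest.warns(UserWarning, match="empty cells"):
            res = two_way_anova([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], a, b)
        assert res["interaction"] is None
        assert res["factor_a"] is not None


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        res = chi_square_independence([[30, 20, 10], [30, 20, 10]])
        assert res.statistic_value == pytest.approx(0.0)

    def test_hand_computed_table(self):
        res = chi_square_independence([[50, 50], [25, 75]])
        assert res.statistic_value == pytest.approx(13.3333333, rel=1e-6)
        assert res.df_pair == (1,)

    def test_degenerate_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[10, 0], [20, 0]])


class TestTukeyKramer:
    def test_two_identical_groups_are_not_distinguished(self):
        vals = np.r_[np.arange(10.0), np.arange(10.0)]
        groups = ["a"] * 10 + ["b"] * 10
        (pair,) = tukey_kramer(vals, groups)
        assert pair.p_adjusted > 0.99

    def test_only_the_shifted_group_differs(self):
        rng = np.random.default_rng(4)
        vals = np.r_[rng.normal(0, 1, 15), rng.normal(0, 1, 12), rng.normal(8, 1, 15)]
        groups = np.r_[["a"] * 15, ["b"] * 12, ["c"] * 15]
        pairs = {(p.group_a, p.group_b): p.p_adjusted for p in tukey_kramer(vals, groups)}
        assert pairs[("a", "b")] > 0.05
        assert pairs[("a", "c")] < 0.05 and pairs[("b", "c")] < 0.05

    def test_adjusted_p_is_conservative(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 36)
        groups = np.repeat(["a", "b", "c"], 12)
        for pair in tukey_kramer(vals, groups):
            va = vals[groups == pair.group_a]
            vb = vals[groups == pair.group_b]
            raw = sps.ttest_ind(va, vb).pvalue
            assert pair.p_adjusted >= raw - 1e-12

    def test_single_group_yields_no_comparisons(self):
        assert tukey_kramer([1.0, 2.0, 3.0], ["a", "a", "a"]) == []


class TestPairedT:
    def test_no_change_gives_t_zero(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic_value == 0.0 and res.p_value == 1.0

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(6)
        pre, post = rng.normal(30, 3, 6), rng.normal(29.5, 3, 6)
        res = paired_t_test(pre, post)
        ref = sps.ttest_rel(post, pre)
        assert res.statistic_value == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df_pair == (5,)

    def test_constant_nonzero_difference_is_flagged_degenerate(self):
        res = paired_t_test([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert np.isinf(res.statistic_value) and res.extra["degenerate"]

    def test_body_mass_stability_at_study_scale(self):
        # per-animal masses at the cohort moments: a 7-day treatment
        # leaves body mass statistically unchanged at n = 6
        rng = np.random.default_rng(7)
        pre = np.r_[rng.normal(30.8, 3.4, 3), rng.normal(22.8, 2.1, 3)]
        post = pre + rng.normal(-0.2, 1.0, 6)
        res = paired_t_test(pre, post)
        assert res.p_value > 0.05


class TestEffectSizes:
    def test_printed_group_means_reproduce_the_reported_effects(self):
        es = effect_sizes(
            {
                "pre_volume": (1411.0, 1248.0),
                "apposition": (66.0, 56.0),
                "innervated_pct": (93.0, 78.0),
                "partial_pct": (7.0, 19.0),
                "mass_by_sex": ((33.3 + 30.8) / 2.0, (22.6 + 22.8) / 2.0),
            }
        )
        assert es.rounded() == {
            "pct_change_pre_volume": 12,
            "pct_change_apposition": 15,
            "pct_change_innervated": 16,
            "fold_partial_denervation": 2.7,
            "pct_sex_mass_difference": 41,
        }

    def test_zero_reference_mean_is_an_error(self):
        with pytest.raises(ValueError):
            effect_sizes({"pre_volume": (0.0, 10.0)})
        with pytest.raises(ValueError):
            effect_sizes({"partial_pct": (0.0, 10.0)})


class TestPowerCheck:
    def test_null_effect_rejects_at_alpha(self):
        power = power_check(0.0, n_per_group=4, reps=2000, seed=0)
        assert abs(power - 0.05) < 0.02

    def test_power_monotone_in_effect_and_n(self):
        p_small = power_check(5.0, n_per_group=4, reps=800, seed=1)
        p_big = power_check(20.0, n_per_group=4, reps=800, seed=1)
        p_more_n = power_check(5.0, n_per_group=12, reps=800, seed=1)
        assert p_big > p_small
        assert p_more_n > p_small

    def test_four_animals_suffice_for_a_20pct_effect(self):
        assert power_check(20.0, n_per_group=4, reps=1000, seed=2) >= 0.8
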