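"""Unit and oracle tests for the group-comparison battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fearcond import stats as st


class TestWelch:
    def test_summary_stats_match_published_sample_table(self):
        # age comparison: 26.80 (6.99, n=203) vs 25.14 (5.50, n=1199)
        r = st.welch_t_from_stats(26.80, 6.99, 203, 25.14, 5.50, 1199)
        assert r.df == pytest.approx(246.1, abs=0.05)
        assert abs(r.statistic) == pytest.approx(3.21, abs=0.015)
        stai = st.welch_t_from_stats(38.73, 9.52, 203, 34.04, 7.83, 1199)
        assert abs(stai.statistic) == pytest.approx(6.65, abs=0.005)
        ads = st.welch_t_from_stats(8.71, 6.31, 203, 6.69, 5.70, 1199)
        assert abs(ads.statistic) == pytest.approx(4.28, abs=0.005)

    def test_identical_groups_give_zero_statistic(self, rng):
        x = rng.normal(size=30)
        r = st.welch_t(x, x.copy())
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_reduces_to_student_under_equal_variance_and_n(self, rng):
        a = rng.normal(size=25)
        b = a + 0.7  # identical sample variance, equal n
        w, s = st.welch_t(a, b), st.student_t_ind(a, b)
        assert w.statistic == pytest.approx(s.statistic, abs=1e-10)
        assert w.df == pytest.approx(s.df, abs=1e-10)

    def test_degenerate_equal_constants_raise(self):
        with pytest.raises(ValueError, match="undefined"):
            st.welch_t([1.0, 1.0, 1.0], [1.0, 1.0])


class TestCohensD:
    def test_published_group_differences(self):
        assert st.cohens_d_from_stats(26.80, 6.99, 203, 25.14, 5.50, 1199) == pytest.approx(0.29, abs=0.005)
        assert st.cohens_d_from_stats(38.73, 9.52, 203, 34.04, 7.83, 1199) == pytest.approx(0.58, abs=0.005)
        assert st.cohens_d_from_stats(8.71, 6.31, 203, 6.69, 5.70, 1199) == pytest.approx(0.35, abs=0.005)

    def test_identical_groups_give_zero(self, rng):
        x = rng.normal(size=20)
        assert st.cohens_d(x, x.copy()) == 0.0

    def test_ci_matches_published_interval(self):
        lo, hi = st.ci_cohens_d(-0.18, 203, 1199)
        assert lo == pytest.approx(-0.33, abs=0.005)
        assert hi == pytest.approx(-0.03, abs=0.005)

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ValueError):
            st.cohens_d([1, 1], [1, 1])


class TestStudentPaired:
    def test_hand_computed_two_group_example(self):
        r = st.student_t_ind([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4

    def test_paired_identical_samples(self, rng):
        x = rng.normal(size=12)
        assert st.paired_t(x, x.copy()).statistic == pytest.approx(0.0)


class TestChiSquare:
    def test_goodness_of_fit_group_sizes(self):
        r = st.chi_square_gof([203, 1199])
        assert r.statistic == pytest.approx(707.57, abs=0.005)
        assert r.df == 1

    def test_2x2_with_continuity_correction(self):
        r = st.chi_square_2x2([[124, 79], [721, 478]], correction=True)
        assert r.statistic == pytest.approx(0.03, abs=0.005)

    def test_proportional_table_gives_zero(self):
        r = st.chi_square_2x2([[20, 40], [10, 20]], correction=False)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError):
            st.chi_square_gof([3, 4], [0, 7])


class TestAnova:
    def test_hand_computed_three_groups(self):
        r = st.one_way_anova([1, 2], [3, 4], [5, 6])
        assert r.statistic == pytest.approx(16.0, abs=1e-10)
        assert r.df == (2.0, 3.0)

    def test_two_groups_equal_t_squared(self, rng):
        a, b = rng.normal(size=15), rng.normal(0.4, 1, size=12)
        f = st.one_way_anova(a, b).statistic
        t = st.student_t_ind(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_equal_means_give_near_zero_f(self):
        r = st.one_way_anova([1.0, 2.0], [1.0, 2.0], [2.0, 1.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)


class TestMixedAnova:
    def test_pure_interaction_pattern(self):
        # +delta on group-1 CS+ only: interaction and both main effects arise
        y11 = np.array([1.51, 1.49])
        y12 = np.array([0.99, 1.02])
        y21 = np.array([1.01, 0.98])
        y22 = np.array([1.02, 0.99])
        res = st.mixed_anova_2x2(y11, y12, y21, y22)
        assert res["interaction"].extra["ss"] > 0
        assert res["interaction"].statistic > 10

    def test_ss_decomposition_is_complete(self, rng):
        y11, y12 = rng.normal(size=8), rng.normal(size=8)
        y21, y22 = rng.normal(size=6), rng.normal(size=6)
        res = st.mixed_anova_2x2(y11, y12, y21, y22)
        parts = (res["group"].extra["ss"] + res["group"].extra["ss_error"]
                 + res["within"].extra["ss"] + res["interaction"].extra["ss"]
                 + res["within"].extra["ss_error"])
        assert parts == pytest.approx(res["group"].extra["ss_total"], rel=1e-10)

    def test_matches_pingouin_split_plot(self, rng):
        pg = pytest.importorskip("pingouin")
        y11, y12 = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        y21, y22 = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        ours = st.mixed_anova_2x2(y11, y12, y21, y22)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(22), 2),
            "group": np.repeat(["a"] * 10 + ["b"] * 12, 2),
            "cs": ["plus", "minus"] * 22,
            "y": np.concatenate([np.stack([y11, y12], 1).ravel(),
                                 np.stack([y21, y22], 1).ravel()]),
        })
        ref = pg.mixed_anova(df, dv="y", within="cs", between="group",
                             subject="subject")
        ref = ref.set_index("Source")["F"]
        assert ours["group"].statistic == pytest.approx(ref["group"], rel=1e-6)
        assert ours["within"].statistic == pytest.approx(ref["cs"], rel=1e-6)
        assert ours["interaction"].statistic == pytest.approx(ref["Interaction"], rel=1e-6)

    def test_constant_data_flagged_degenerate(self):
        res = st.mixed_anova_2x2([1, 1], [1, 1], [1, 1], [1, 1])
        assert res["group"].extra.get("degenerate")


class TestYuen:
    def test_zero_trim_equals_welch(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.5, 2, size=25)
        y, w = st.yuen_t(a, b, trim=0.0), st.welch_t(a, b)
        assert y.statistic == pytest.approx(w.statistic, abs=1e-10)
        assert y.df == pytest.approx(w.df, abs=1e-10)
        assert y.p == pytest.approx(w.p, abs=1e-10)

    def test_identical_samples_zero_statistic_and_xi(self, rng):
        x = rng.normal(size=25)
        r = st.yuen_t(x, x.copy(), trim=0.2)
        assert r.statistic == pytest.approx(0.0)
        assert r.effect_size == pytest.approx(0.0)

    def test_outlier_resistant_vs_explicit_trim_oracle(self):
        a = np.arange(1.0, 21.0)
        b = np.r_[np.arange(1.0, 19.0), 1000.0, 1000.0]
        r = st.yuen_t(a, b, trim=0.2)
        # explicit oracle: trim 4 per tail, winsorize, Yuen formulas
        def yuen_oracle(x, y, g):
            x, y = np.sort(x), np.sort(y)
            tx = x[g:-g].mean()
            ty = y[g:-g].mean()
            wx = np.r_[[x[g]] * g, x[g:-g], [x[-g - 1]] * g]
            wy = np.r_[[y[g]] * g, y[g:-g], [y[-g - 1]] * g]
            hx, hy = len(x) - 2 * g, len(y) - 2 * g
            dx = (len(x) - 1) * wx.var(ddof=1) / (hx * (hx - 1))
            dy = (len(y) - 1) * wy.var(ddof=1) / (hy * (hy - 1))
            return (tx - ty) / np.sqrt(dx + dy)
        assert r.statistic == pytest.approx(yuen_oracle(a, b, 4), abs=1e-10)

    def test_statistic_matches_scipy_trimmed_ttest(self, rng):
        a, b = rng.normal(size=30), rng.normal(0.3, 1.5, size=24)
        r = st.yuen_t(a, b, trim=0.2)
        ref = sps.ttest_ind(a, b, trim=0.2, equal_var=False)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_xi_in_unit_interval_and_grows_with_separation(self, rng):
        a = rng.normal(size=50)
        small = st.yuen_t(a, a + 0.2, trim=0.2).effect_size
        large = st.yuen_t(a, a + 2.0, trim=0.2).effect_size
        assert 0 <= small <= large <= 1

    def test_excessive_trim_raises(self):
        with pytest.raises(ValueError):
            st.yuen_t([1, 2, 3], [4, 5, 6], trim=0.4)


class TestRegression:
    def test_hc3_matches_bruteforce_leverage_loop(self, rng):
        n, p = 40, 3
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=n) * (1 + np.abs(X["b"]))
        fit = st.ols_hc3(y, X)["fit"]
        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        e = y - Xc @ beta
        H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
        h = np.diag(H)
        meat = Xc.T @ np.diag(e**2 / (1 - h) ** 2) @ Xc
        cov = np.linalg.inv(Xc.T @ Xc) @ meat @ np.linalg.inv(Xc.T @ Xc)
        np.testing.assert_allclose(fit.bse.to_numpy() if hasattr(fit.bse, "to_numpy") else fit.bse,
                                   np.sqrt(np.diag(cov)), rtol=1e-8)

    def test_homoskedastic_hc3_close_to_classical(self, rng):
        n = 10_000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 0.5 * X["x"].to_numpy() + rng.normal(size=n)
        robust = st.ols_hc3(y, X, robust=True)["se"]["x"]
        classical = st.ols_hc3(y, X, robust=False)["se"]["x"]
        assert robust == pytest.approx(classical, rel=0.10)

    def test_binary_predictor_equals_pooled_t(self, rng):
        g = np.r_[np.zeros(20), np.ones(25)]
        y = rng.normal(size=45) + 0.8 * g
        fit = st.ols_hc3(y, pd.DataFrame({"g": g}), robust=False)
        t_reg = float(fit["t"]["g"])
        t_pooled = st.student_t_ind(y[g == 1], y[g == 0]).statistic
        assert t_reg == pytest.approx(t_pooled, abs=1e-10)

    def test_collinear_design_raises_naming_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            st.ols_hc3(rng.normal(size=30), X)


class TestVif:
    def test_orthogonal_predictors_give_unity(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]})
        v = st.vif(X)
        assert v["a"] == pytest.approx(1.0, abs=1e-10)
        assert v["b"] == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_for_two_correlated_predictors(self, rng):
        n = 5000
        a = rng.normal(size=n)
        b = 0.9403 * a + np.sqrt(1 - 0.9403**2) * rng.normal(size=n)
        r = np.corrcoef(a, b)[0, 1]
        v = st.vif(pd.DataFrame({"a": a, "b": b}))
        expected = 1 / (1 - r**2)
        assert v["a"] == pytest.approx(expected, rel=1e-6)
        # at r ~= 0.94 the VIF sits near the 8.6 regime reported for
        # strongly co-occurring abuse/neglect composites
        assert 6.5 < v["a"] < 11

    def test_single_predictor_raises(self):
        with pytest.raises(ValueError):
            st.vif(pd.DataFrame({"a": [1.0, 2, 3]}))


class TestHolm:
    def test_hand_stepdown_example(self):
        adj = st.holm_correct([0.01, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert st.holm_correct([0.031])[0] == pytest.approx(0.031)

    def test_ties_capped_at_one(self):
        np.testing.assert_allclose(st.holm_correct([0.3, 0.3, 0.3]), [0.9, 0.9, 0.9])
        np.testing.assert_allclose(st.holm_correct([0.6, 0.6]), [1.0, 1.0])

    def test_order_invariance(self, rng):
        p = rng.random(9)
        perm = rng.permutation(9)
        adj = st.holm_correct(p)
        adj_perm = st.holm_correct(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)

    def test_bounds_vs_raw_and_bonferroni(self, rng):
        p = rng.random(7)
        adj = st.holm_correct(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(len(p) * p, 1.0) + 1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            st.holm_correct([0.5, 1.2])


class TestEffectConversion:
    def test_r_to_d_closed_form(self):
        assert st.effect_to_abs_d("r", 0.0995)["abs_d"] == pytest.approx(0.2, abs=1e-3)

    def test_zero_t_gives_zero(self):
        assert st.effect_to_abs_d("t", 0.0, n1=10, n2=12)["abs_d"] == 0.0

    def test_d_t_roundtrip_equal_groups(self):
        d0 = 0.37
        n = 40
        t = d0 / np.sqrt(1 / n + 1 / n)
        assert st.effect_to_abs_d("t", t, n1=n, n2=n)["abs_d"] == pytest.approx(d0)

    def test_f_with_multiple_numerator_df_rejected(self):
        with pytest.raises(ValueError, match="F\\(1"):
            st.effect_to_abs_d("f", 4.2, df=100, df_num=3)

    def test_verdicts_against_main_ci(self):
        res = st.compare_to_main_ci({"a": 0.18, "b": 0.34, "c": 0.33},
                                    (0.03, 0.33))
        assert res["verdicts"] == {"a": "inside", "b": "outside", "c": "inside"}
        assert res["any_outside"]


class TestNullCalibration:
    def test_welch_and_yuen_type_I_error_near_nominal(self):
        """Under a common-normal null both tests reject at ~5%."""
        rng = np.random.default_rng(7)
        reps = 2000
        rej_w = rej_y = 0
        for _ in range(reps):
            a, b = rng.normal(size=(2, 30))
            if st.welch_t(a, b).p < 0.05:
                rej_w += 1
            if st.yuen_t(a, b, trim=0.2).p < 0.05:
                rej_y += 1
        assert rej_w / reps == pytest.approx(0.05, abs=0.015)
        assert rej_y / reps == pytest.approx(0.05, abs=0.015)
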