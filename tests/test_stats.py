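"""Inference layer against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from vmrlearn import stats

from _oracles import (
    gg_epsilon,
    holm_by_hand,
    mixed_anova_ss,
    pooled_t_by_hand,
    power_scan,
    soft_threshold,
)


def long_table(Y, groups):
    rows = []
    for s in range(Y.shape[0]):
        for lv in range(Y.shape[1]):
            rows.append(dict(subj=s, grp=groups[s], lvl=f"L{lv}", y=Y[s, lv]))
    return pd.DataFrame(rows)


def random_mixed_table(rng, n_per_group=8, k=4):
    n = 2 * n_per_group
    groups = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    base = rng.normal(size=(n, 1))
    Y = base + rng.normal(size=(n, k)) + np.linspace(0, 1, k) * rng.normal()
    return Y, groups


class TestMixedAnova:
    def test_identical_values_zero_f(self):
        Y = np.ones((10, 3))
        df = long_table(Y, ["A"] * 5 + ["B"] * 5)
        res = stats.mixed_anova(df, dv="y", within="lvl", between="grp", subject="subj")
        for eff in res.values():
            assert np.isnan(eff.F) or eff.F == pytest.approx(0.0, abs=1e-10)

    def test_two_levels_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(12, 2))
        df = long_table(Y, ["A"] * 6 + ["B"] * 6)
        res = stats.mixed_anova(df, dv="y", within="lvl", between="grp", subject="subj")
        assert res["within"].epsilon_gg == 1.0
        assert not res["within"].gg_corrected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Y, groups = random_mixed_table(rng)
        df = long_table(Y, groups)
        res = stats.mixed_anova(df, dv="y", within="lvl", between="grp", subject="subj")
        oracle = mixed_anova_ss(Y, groups)
        for eff in ("between", "within", "interaction"):
            f_orc, df1_orc, df2_orc = oracle[eff]
            assert res[eff].F == pytest.approx(f_orc, abs=1e-6)
            if not res[eff].gg_corrected:
                assert res[eff].df1 == pytest.approx(df1_orc)
                assert res[eff].df2 == pytest.approx(df2_orc)

    def test_gg_correction_applied_when_nonspherical(self):
        rng = np.random.default_rng(1)
        n = 40
        groups = ["A"] * 20 + ["B"] * 20
        # strongly heteroscedastic levels -> sphericity violated
        Y = rng.normal(size=(n, 4)) * np.array([0.2, 0.2, 0.2, 5.0])
        Y[:, 3] += np.linspace(0, 2, n)
        df = long_table(Y, groups)
        res = stats.mixed_anova(df, dv="y", within="lvl", between="grp", subject="subj")
        w = res["within"]
        assert w.mauchly_p < 0.05
        assert w.gg_corrected
        assert w.df1 == pytest.approx(w.epsilon_gg * 3)
        assert w.df2 == pytest.approx(w.epsilon_gg * 3 * 38)

    def test_incomplete_participants_dropped(self):
        rng = np.random.default_rng(2)
        Y, groups = random_mixed_table(rng)
        df = long_table(Y, groups)
        df = df[~((df.subj == 0) & (df.lvl == "L3"))]  # subject 0 missing a level
        res = stats.mixed_anova(df, dv="y", within="lvl", between="grp", subject="subj")
        oracle = mixed_anova_ss(Y[1:], groups[1:])
        assert res["within"].F == pytest.approx(oracle["within"][0], abs=1e-6)


class TestMauchlyGG:
    def test_two_levels_trivial(self):
        out = stats.mauchly_gg(np.random.default_rng(0).normal(size=(10, 2)))
        assert out.W == 1.0 and out.epsilon_gg == 1.0

    def test_matches_pingouin_single_group(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(15, 4)) * np.array([1.0, 1.5, 0.5, 2.0])
        df = long_table(Y, ["A"] * 15)
        mine = stats.mauchly_gg(Y)
        ref = pg.sphericity(df, dv="y", subject="subj", within="lvl")
        eps_ref = pg.epsilon(df, dv="y", subject="subj", within="lvl", correction="gg")
        assert mine.W == pytest.approx(ref.W, abs=1e-9)
        assert mine.chi2 == pytest.approx(ref.chi2, abs=1e-9)
        assert mine.epsilon_gg == pytest.approx(eps_ref, abs=1e-9)

    def test_epsilon_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(20, 5)) * np.array([1, 2, 0.5, 3, 1])
        assert stats.mauchly_gg(Y).epsilon_gg == pytest.approx(gg_epsilon(Y), abs=1e-9)

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(5)
        shared = rng.normal(size=(400, 1))
        Y = shared + rng.normal(size=(400, 4))
        assert stats.mauchly_gg(Y).epsilon_gg > 0.95

    def test_epsilon_floor(self):
        # rank-one covariance: maximal non-sphericity -> epsilon = 1/(k-1)
        rng = np.random.default_rng(6)
        base = rng.normal(size=(30, 1))
        Y = base * np.array([1.0, 2.0, 4.0, 8.0]) + 1e-9 * rng.normal(size=(30, 4))
        eps = stats.mauchly_gg(Y).epsilon_gg
        assert eps == pytest.approx(1 / 3, abs=1e-3)


class TestHolm:
    def test_single_test_unchanged(self):
        assert stats.holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_two_tests_by_hand(self):
        adj = stats.holm_adjust([0.01, 0.04])
        assert adj == pytest.approx([0.02, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_longhand_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=rng.integers(2, 9))
        assert stats.holm_adjust(p) == pytest.approx(holm_by_hand(p), abs=1e-12)

    def test_equal_ps_scaled_then_monotone(self):
        adj = stats.holm_adjust([0.02, 0.02, 0.02])
        assert adj == pytest.approx([0.06, 0.06, 0.06])

    def test_posthoc_contrasts(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        rows = stats.posthoc_holm([(x, y, False), (x, x + 0.01, True)])
        assert rows[0]["df"] == 38
        raw = [r["p_raw"] for r in rows]
        assert [r["p_holm"] for r in rows] == pytest.approx(list(holm_by_hand(raw)))


class TestIndependentT:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = stats.independent_t(x, x)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_toy_vs_hand_computation(self):
        x = [4.1, 5.2, 6.3, 5.5, 4.9]
        y = [3.1, 4.0, 3.5, 4.4]
        t, df, p = stats.independent_t(x, y)
        t_o, df_o, p_o = pooled_t_by_hand(x, y)
        assert (t, df, p) == pytest.approx((t_o, df_o, p_o), abs=1e-12)

    def test_df_for_31_and_28(self):
        rng = np.random.default_rng(8)
        _, df, _ = stats.independent_t(rng.normal(size=31), rng.normal(size=28))
        assert df == 57

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.independent_t([1.0, 1.0], [1.0, 1.0])


class TestLasso:
    def orthonormal_design(self, rng, n=64, p=6):
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        return np.sqrt(n) * Q  # X.T @ X = n * I

    def test_lambda_max_kills_all_coefficients(self):
        rng = np.random.default_rng(9)
        X = self.orthonormal_design(rng)
        y = rng.normal(size=64)
        yc = y - y.mean()
        lmax = np.max(np.abs(X.T @ yc)) / 64
        coef = stats.lasso_fit(X, yc, lmax * 1.0001)
        assert np.allclose(coef, 0.0, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.05, 0.2, 0.6])
    def test_orthonormal_soft_threshold_oracle(self, lam):
        rng = np.random.default_rng(10)
        X = self.orthonormal_design(rng)
        beta = np.array([1.0, -0.5, 0.3, 0.0, 0.0, 0.8])
        y = X @ beta + rng.normal(0, 0.1, 64)
        yc = y - y.mean()
        ols = X.T @ yc / 64
        assert stats.lasso_fit(X, yc, lam) == pytest.approx(
            soft_threshold(ols, lam), abs=1e-6
        )

    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert stats.lasso_fit(X, y, 0.0) == pytest.approx(ols, abs=1e-6)

    def test_l1_norm_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        norms = [
            np.abs(stats.lasso_fit(X, y - y.mean(), lam)).sum()
            for lam in np.logspace(-3, 0.5, 12)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_support_nonincreasing_on_orthonormal_design(self):
        rng = np.random.default_rng(13)
        X = self.orthonormal_design(rng)
        beta = np.array([1.0, -0.5, 0.3, 0.1, 0.0, 0.8])
        y = X @ beta
        yc = y - y.mean()
        supports = [
            int((np.abs(stats.lasso_fit(X, yc, lam)) > 1e-10).sum())
            for lam in np.logspace(-3, 0.3, 10)
        ]
        assert all(a >= b for a, b in zip(supports, supports[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stats.lasso_fit(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]), 0.1)


class TestCV1SE:
    def test_lambda_1se_not_below_lambda_min(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(80, 6))
        y = X[:, 0] + rng.normal(size=80)
        res = stats.cv_1se(X, y, seed=0)
        assert res.lambda_1se >= res.lambda_min

    def test_pure_noise_mostly_empty(self):
        empty = 0
        for i in range(20):
            rng = np.random.default_rng(1000 + i)
            X = rng.standard_normal((100, 8))
            y = rng.standard_normal(100)
            res = stats.cv_1se(X, y, seed=i)
            empty += len(res.selected) == 0
        assert empty >= 18

    def test_dominant_predictor_always_selected(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(2000 + i)
            X = rng.standard_normal((100, 8))
            y = X[:, 3] + rng.normal(0, 0.1, 100)
            res = stats.cv_1se(X, y, seed=i)
            hits += "x3" in res.selected
        assert hits == 20

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 5))
        y = X[:, 1] + rng.normal(size=60)
        a = stats.cv_1se(X, y, seed=3)
        b = stats.cv_1se(X, y, seed=3)
        assert a.lambda_1se == b.lambda_1se and a.selected == b.selected


class TestOLSFinal:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = stats.ols_final(x, 2.0 * x, feature_names=["x"])
        assert res.params["x"] == pytest.approx(2.0)
        assert res.r2_adj == pytest.approx(1.0)

    def test_single_regressor_vs_normal_equations(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(size=40)
        res = stats.ols_final(x, y, feature_names=["x"])
        beta1 = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        beta0 = y.mean() - beta1 * x.mean()
        assert res.params["x"] == pytest.approx(beta1, abs=1e-10)
        assert res.params["const"] == pytest.approx(beta0, abs=1e-10)

    def test_null_selection_intercept_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = stats.ols_final(None, y)
        assert res.params == {"const": pytest.approx(2.5)}
        assert res.r2_adj == 0.0

    def test_collinear_selection_rejected(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="condition"):
            stats.ols_final(X, x)


class TestPower:
    def test_paper_configuration(self):
        assert stats.power_regression_n(7, 0.33, 0.05, 0.80) == 51

    def test_single_predictor_vs_scan_oracle(self):
        assert stats.power_regression_n(1, 0.33, 0.05, 0.80) == power_scan(1, 0.33, 0.05, 0.80)

    def test_seven_predictors_vs_scan_oracle(self):
        assert stats.power_regression_n(7, 0.33, 0.05, 0.80) == power_scan(7, 0.33, 0.05, 0.80)

    def test_huge_effect_approaches_df_floor(self):
        assert stats.power_regression_n(3, 100.0, 0.05, 0.80) <= 7

    def test_f2_from_r2(self):
        assert stats.f2_from_r2(0.25) == pytest.approx(1 / 3)
        assert round(stats.f2_from_r2(0.25), 2) == 0.33
        assert stats.f2_from_r2(0.0) == 0.0
        assert stats.f2_from_r2(0.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            stats.f2_from_r2(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.power_regression_n(7, -0.1)
        with pytest.raises(ValueError):
            stats.power_regression_n(7, 0.33, alpha=1.5)


class TestDesignBuild:
    def test_interaction_columns_are_products(self, small_cohort):
        from vmrlearn.pipeline import build_feature_table

        table = build_feature_table(small_cohort, flag_outliers=False)
        design, _ = stats.build_design(table)
        assert design.shape[1] == 13
        for f in stats.EEG_FEATURES:
            assert np.allclose(
                design[f"cond_x_{f}"], design["condition_code"] * design[f]
            )

    def test_rows_with_missing_features_dropped(self, small_cohort):
        from vmrlearn.pipeline import build_feature_table

        table = build_feature_table(small_cohort, flag_outliers=False)
        table.loc[0, "frn_early"] = np.nan
        design, keep = stats.build_design(table)
        assert design.shape[0] == len(table) - 1
        assert not keep[0]
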