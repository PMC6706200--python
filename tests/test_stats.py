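import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from codnet import stats
from codnet.synthetic import reference_weekly_sst, simulate_nb_counts
from oracles import welch_f_direct


class TestTransforms:
    def test_reference_transforms(self):
        env = pd.DataFrame({
            "sst": [16.3], "wind_speed": [1.0], "par": [4.0],
            "wind_direction": [270.0], "sea_level": [35.0],
        })
        out = stats.transform_predictors(env)
        assert out["log_wind_speed"].iloc[0] == 0.0
        assert out["sqrt_par"].iloc[0] == 2.0
        assert out["sst"].iloc[0] == 16.3
        assert out["wind_direction"].iloc[0] == 270.0

    def test_nonpositive_wind_speed_rejected(self):
        env = pd.DataFrame({"sst": [10.0], "wind_speed": [0.0], "par": [1.0],
                            "wind_direction": [0.0], "sea_level": [0.0]})
        with pytest.raises(ValueError, match="wind_speed"):
            stats.transform_predictors(env)


class TestVIF:
    def test_orthogonal_covariates_all_retained_at_unit_vif(self):
        n = 64
        x = np.tile([1.0, -1.0], n // 2)
        y = np.repeat([1.0, -1.0], n // 2)
        retained, table = stats.vif_screen(pd.DataFrame({"x": x, "y": y}))
        assert list(retained.columns) == ["x", "y"]
        assert np.allclose(table["vif"], 1.0)

    def test_correlated_pair_vif_matches_closed_form_and_one_dropped(self):
        rng = np.random.default_rng(1)
        n = 4000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        retained, table = stats.vif_screen(pd.DataFrame({"x": x, "y": y}), threshold=3.0)
        # VIF = 1/(1-r^2) with r ~ 0.9 -> ~5.26
        assert table["vif"].iloc[0] == pytest.approx(5.26, rel=0.15)
        assert len(retained.columns) == 1

    def test_duplicate_covariate_has_infinite_vif_and_goes_first(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "x2": x.copy(), "z": z})
        retained, table = stats.vif_screen(df)
        dropped = table.loc[table["dropped"], "covariate"].tolist()
        assert dropped and dropped[0] in {"x", "x2"}
        assert np.isinf(table.loc[table["step"] == 0, "vif"]).sum() == 2
        assert "z" in retained.columns


class TestWelchAnova:
    def test_equal_means_give_f_near_zero(self):
        g = [np.array([5.0, 5.1, 4.9, 5.0]), np.array([5.0, 4.9, 5.1, 5.0]),
             np.array([5.05, 4.95, 5.0, 5.0])]
        res = stats.welch_anova(g)
        assert res.statistic < 1.0 and res.pvalue > 0.3

    def test_reduces_to_classical_f_under_equal_variance_and_n(self):
        # with equal variances and sizes the Welch correction term is
        # 1 + O(1/n), so the two statistics coincide as n grows
        rng = np.random.default_rng(3)
        g = [rng.normal(i * 0.5, 1.0, 200) for i in range(3)]
        g = [(x - x.mean()) / x.std(ddof=1) + i * 0.7 for i, x in enumerate(g)]
        res = stats.welch_anova(g)
        classical = sps.f_oneway(*g)
        assert res.statistic == pytest.approx(classical.statistic, rel=5e-3)

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(4)
        g = [np.round(rng.normal(m, s, 10), 6) for m, s in [(0, 1), (0.8, 2), (1.5, 0.5)]]
        res = stats.welch_anova(g)
        f, df1, df2 = welch_f_direct([list(x) for x in g])
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.df[1] == pytest.approx(df2, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(m, s, n) for m, s, n in
                               [(0, 1, 10), (1, 2, 14), (0.5, 0.6, 8)]])
        grp = np.repeat(["a", "b", "c"], [10, 14, 8])
        df = pd.DataFrame({"v": vals, "g": grp})
        res = stats.welch_anova([vals[grp == k] for k in "abc"])
        ref = pg.welch_anova(data=df, dv="v", between="g")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.pvalue == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


class TestGamesHowell:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = stats.games_howell([a, a.copy()])
        assert res.table["q"].iloc[0] == 0.0
        assert res.table["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_two_group_decision_agrees_with_welch_t(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(0, 1, 12)
            b = rng.normal(rng.uniform(0, 1.2), 2, 9)
            gh = stats.games_howell([a, b]).table["pvalue"].iloc[0]
            t = stats.site_comparison(a, b, method="t").pvalue
            assert (gh < 0.05) == (t < 0.05)
            assert gh == pytest.approx(t, rel=0.02)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(m, s, n) for m, s, n in
                               [(0, 1, 10), (1.5, 2, 14), (0.5, 0.6, 8)]])
        grp = np.repeat(["a", "b", "c"], [10, 14, 8])
        res = stats.games_howell([vals[grp == k] for k in "abc"], labels=list("abc"))
        ref = pg.pairwise_gameshowell(data=pd.DataFrame({"v": vals, "g": grp}), dv="v", between="g")
        mine = res.table.set_index(["group1", "group2"])["pvalue"]
        for _, r in ref.iterrows():
            assert mine[(r["A"], r["B"])] == pytest.approx(r["pval"], abs=1e-6)

    def test_separated_groups_all_pairwise_significant(self):
        rng = np.random.default_rng(8)
        g = [rng.normal(m, 0.5, 15) for m in (0.0, 2.0, 5.0)]
        res = stats.games_howell(g)
        assert (res.table["pvalue"] < 0.05).all()


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(8.0)
        assert stats.spearman_test(x, x**3).statistic == pytest.approx(1.0)
        assert stats.spearman_test(x, -x).statistic == pytest.approx(-1.0)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(size=8)
        exact = stats.spearman_test(x, y, method="exact")
        perm = stats.spearman_test(x, y, method="permutation", n_permutations=20000, seed=0)
        assert perm.pvalue == pytest.approx(exact.pvalue, abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.spearman_test(np.ones(6), np.arange(6.0))


class TestSiteComparison:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert stats.site_comparison(a, a.copy(), "t").pvalue == pytest.approx(1.0)
        assert stats.site_comparison(a, a.copy(), "wilcoxon").pvalue == pytest.approx(1.0)

    def test_disjoint_ranges_hit_the_rank_sum_floor(self):
        a, b = np.arange(4.0), np.arange(10.0, 14.0)
        res = stats.site_comparison(a, b, "wilcoxon")
        # minimal attainable two-sided p for n=m=4: 2 / C(8,4)
        assert res.pvalue == pytest.approx(2 / 70, rel=1e-6)

    def test_large_sample_shift_detected(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 200), rng.normal(0.6, 1, 200)
        assert stats.site_comparison(a, b, "t").pvalue < 1e-4
        assert stats.site_comparison(a, b, "wilcoxon").pvalue < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.site_comparison([], [1.0, 2.0], "t")


# Reference values for the frozen fixture (15 subjects x 10 weeks, seed 42)
# computed once with an independent TMB-based mixed-model fitter.
_ORACLE_NB = {"int": -0.226542, "sst": 0.194584, "se_sst": 0.040115,
              "theta": 1.351396, "sigma_b": 0.743985}
_ORACLE_POIS = {"int": -0.379475, "sst": 0.201509, "se_sst": 0.011247,
                "sigma_b": 0.831286}


class TestNBGLMM:
    def test_matches_independent_fitter_on_frozen_fixture(self, glmm_fixture):
        y, X, g = glmm_fixture
        fit = stats.fit_nb_glmm(y, X, g)
        assert fit.converged
        assert fit.coef("(Intercept)") == pytest.approx(_ORACLE_NB["int"], abs=0.01)
        assert fit.coef("SST") == pytest.approx(_ORACLE_NB["sst"], abs=0.002)
        assert fit.terms.loc["SST", "se"] == pytest.approx(_ORACLE_NB["se_sst"], abs=0.002)
        assert fit.theta == pytest.approx(_ORACLE_NB["theta"], rel=0.02)
        assert fit.sigma_b == pytest.approx(_ORACLE_NB["sigma_b"], rel=0.05)

    def test_poisson_limit_matches_independent_poisson_glmm(self, glmm_fixture):
        y, X, g = glmm_fixture
        fit = stats.fit_nb_glmm(y, X, g, fixed_theta=1e8)
        assert fit.coef("(Intercept)") == pytest.approx(_ORACLE_POIS["int"], abs=0.01)
        assert fit.coef("SST") == pytest.approx(_ORACLE_POIS["sst"], abs=0.002)
        assert fit.terms.loc["SST", "se"] == pytest.approx(_ORACLE_POIS["se_sst"], abs=0.001)
        assert fit.sigma_b == pytest.approx(_ORACLE_POIS["sigma_b"], rel=0.05)

    def test_intercept_only_poisson_limit_recovers_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5.0, 200)
        fit = stats.fit_nb_glmm(y, None, np.zeros(200, dtype=int), fixed_theta=1e8)
        assert np.exp(fit.coef("(Intercept)")) == pytest.approx(y.mean(), rel=1e-3)

    def test_slope_recovery_at_reference_design(self):
        rng = np.random.default_rng(100)
        y, X, g = simulate_nb_counts(rng, reference_weekly_sst(21))
        fit = stats.fit_nb_glmm(y, X, g)
        assert fit.converged
        assert fit.coef("SST") == pytest.approx(0.25, abs=0.05)

    def test_quadrature_is_converged_between_15_and_25_nodes(self, glmm_fixture):
        y, X, g = glmm_fixture
        f15 = stats.fit_nb_glmm(y, X, g, n_quad=15)
        f25 = stats.fit_nb_glmm(y, X, g, n_quad=25)
        assert np.allclose(f15.terms["estimate"], f25.terms["estimate"], atol=1e-3)

    def test_objective_trace_is_monotone(self, glmm_fixture):
        y, X, g = glmm_fixture
        fit = stats.fit_nb_glmm(y, X, g)
        trace = np.array(fit.nll_trace)
        assert len(trace) > 2
        assert (np.diff(trace) <= 1e-6).all()

    def test_all_zero_response_flagged(self):
        fit = stats.fit_nb_glmm(np.zeros(30, int), None, np.repeat([0, 1, 2], 10))
        assert not fit.estimable and "all-zero" in fit.message

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            stats.fit_nb_glmm(np.array([0.5, 1.0]), None, np.array([0, 1]))


class TestZINBGLMM:
    def test_reduces_to_nb_without_structural_zeros(self, glmm_fixture):
        y, X, g = glmm_fixture
        nb = stats.fit_nb_glmm(y, X, g)
        zi = stats.fit_zinb_glmm(y, X, g)
        assert zi.zi_prob < 0.02
        assert zi.coef("SST") == pytest.approx(nb.coef("SST"), abs=0.005)

    def test_recovers_structural_zero_fraction(self):
        errs = []
        for r in range(8):
            rng = np.random.default_rng(200 + r)
            y, X, g = simulate_nb_counts(rng, reference_weekly_sst(21), zi_prob=0.3)
            fit = stats.fit_zinb_glmm(y, X, g)
            if fit.converged:
                errs.append(fit.zi_prob - 0.3)
        assert len(errs) >= 6
        assert abs(np.mean(errs)) < 0.1

    def test_no_zero_response_is_non_identifiable(self):
        rng = np.random.default_rng(12)
        y = rng.poisson(20, 40) + 1
        fit = stats.fit_zinb_glmm(y, None, np.repeat([0, 1], 20))
        assert not fit.estimable and "zero" in fit.message
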