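import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thermoresp as tr
from thermoresp.stats_models import (StatsError, fit_lmm, lrt_random_intercept,
                                     wald_chisq)


class TestAicc:
    def test_formula_arithmetic(self):
        # k=2, n=100, loglik=-50 -> 104 + 12/97
        assert tr.aicc(-50.0, 2, 100) == pytest.approx(104 + 12 / 97,
                                                       rel=1e-12)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 3
        assert abs(tr.aicc(-50.0, 3, 10**6) - aic) < 1e-4

    def test_small_sample_guard(self):
        assert tr.aicc(-50.0, 10, 11) == np.inf


class TestBonferroni:
    def test_arithmetic(self):
        assert tr.bonferroni(0.004, 10) == pytest.approx(0.04, rel=1e-12)

    def test_monotone_and_bounded(self):
        p = np.linspace(0, 1, 51)
        adj = tr.bonferroni(p, 7)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj <= 1.0)


class TestWelchAnova:
    def _groups(self, seed=0):
        rng = np.random.default_rng(seed)
        return {g: rng.normal(m, s, n) for g, m, s, n in
                zip("abcd", (0, 0.5, 1, 0), (1, 2, 0.5, 1.5), (8, 12, 9, 15))}

    def test_identical_groups_give_zero_f(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10)
        res = tr.welch_anova({"a": x, "b": x.copy(), "c": x.copy()})
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_reduce_to_welch_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 11), rng.normal(0.8, 2.5, 17)
        res = tr.welch_anova({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res["F"] == pytest.approx(t**2, rel=1e-9)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        groups = self._groups()
        df = pd.DataFrame([(g, v) for g, xs in groups.items() for v in xs],
                          columns=["g", "y"])
        ref = pg.welch_anova(data=df, dv="y", between="g")
        res = tr.welch_anova(groups)
        assert res["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res["df2"] == pytest.approx(float(ref["ddof2"].iloc[0]),
                                           rel=1e-9)
        assert res["p"] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(StatsError):
            tr.welch_anova({"a": [1.0, 1.0], "b": [1.0, 2.0]})
        with pytest.raises(StatsError):
            tr.welch_anova({"a": [1.0]})


class TestGamesHowell:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 12)
        out = tr.games_howell({"a": x, "b": x + 1e-9, "c": x - 1e-9})
        assert (out["p"] > 0.999).all()

    def test_two_groups_agree_with_welch_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1.2, 2, 14)
        out = tr.games_howell({"a": a, "b": b})
        _, p = sps.ttest_ind(a, b, equal_var=False)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(m, s, n) for g, m, s, n in
                  zip("abcd", (0, 1, 0.5, 2), (1, 2, 1.5, 0.8), (9, 13, 11, 8))}
        df = pd.DataFrame([(g, v) for g, xs in groups.items() for v in xs],
                          columns=["g", "y"])
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        out = tr.games_howell(groups)
        ref = ref.sort_values(["A", "B"]).reset_index(drop=True)
        np.testing.assert_allclose(out["df"], ref["df"], rtol=1e-9)
        np.testing.assert_allclose(out["p"], ref["pval"], rtol=1e-5,
                                   atol=1e-8)


class TestBalanceChecks:
    def _birds(self, masses=None, ages=None):
        n = 20
        methods = ["IP", "CL", "SC", "CU", "C"] * 4
        return pd.DataFrame({
            "method": methods,
            "mass_capture": masses if masses is not None else [17.0] * n,
            "mass_pre": masses if masses is not None else [16.7] * n,
            "mass_post": masses if masses is not None else [15.9] * n,
            "age": ages if ages is not None else ["2cy", "3cy+"] * 10,
            "sex": ["F", "M"] * 10})

    def test_identical_masses_give_f_zero(self):
        out = tr.balance_checks(self._birds())
        assert out["mass_capture"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["mass_capture"]["p"] == pytest.approx(1.0)

    def test_perfectly_balanced_table_gives_chisq_zero(self):
        out = tr.balance_checks(self._birds())
        assert out["age"]["chisq"] == pytest.approx(0.0, abs=1e-12)
        assert out["age"]["p"] == pytest.approx(1.0)

    def test_chi_squared_matches_hand_computation(self):
        ages = ["2cy"] * 12 + ["3cy+"] * 8
        birds = self._birds(ages=ages)
        tab = pd.crosstab(birds["age"], birds["method"]).to_numpy()
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        chi2_hand = float(((tab - expected) ** 2 / expected).sum())
        out = tr.balance_checks(birds)
        assert out["age"]["chisq"] == pytest.approx(chi2_hand, rel=1e-12)


def _toy_lmm_data(seed=0, n_groups=30, reps=3, beta=(1.0, 0.5),
                  sigma_b=0.7, sigma_e=0.4):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma_b)
        for _ in range(reps):
            x = rng.normal()
            y = beta[0] + beta[1] * x + u + rng.normal(0, sigma_e)
            rows.append({"bird_id": f"g{g}", "x": x, "y": y,
                         "method": "IP", "t_air": 5.0, "age": "2cy"})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_homoscedastic_ml_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = _toy_lmm_data()
        fit = fit_lmm(df, "y", ["x"], [], ["x"], variance_by=None,
                      method="ML")
        ref = smf.mixedlm("y ~ x", df, groups=df["bird_id"]).fit(reml=False)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-6)
        np.testing.assert_allclose(fit.beta, ref.fe_params.to_numpy(),
                                   rtol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov_beta)), ref.bse_fe.to_numpy(), rtol=1e-3)

    def test_reml_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = _toy_lmm_data(seed=1)
        fit = fit_lmm(df, "y", ["x"], [], ["x"], variance_by=None,
                      method="REML")
        ref = smf.mixedlm("y ~ x", df, groups=df["bird_id"]).fit(reml=True)
        np.testing.assert_allclose(fit.beta, ref.fe_params.to_numpy(),
                                   rtol=1e-4)
        assert fit.sigma_b == pytest.approx(
            np.sqrt(float(ref.cov_re.iloc[0, 0])), rel=1e-3)

    def test_recovers_heteroscedastic_residual_sds(self):
        rng = np.random.default_rng(6)
        rows = []
        sds = {"IP": 0.2, "CU": 1.0}
        for g in range(120):
            m = "IP" if g % 2 else "CU"
            u = rng.normal(0, 0.5)
            for _ in range(3):
                rows.append({"bird_id": f"g{g}", "method": m,
                             "y": 1.0 + u + rng.normal(0, sds[m])})
        df = pd.DataFrame(rows)
        fit = fit_lmm(df, "y", ["method"], ["method"], [], variance_by="method")
        assert fit.resid_sd["IP"] == pytest.approx(0.2, rel=0.2)
        assert fit.resid_sd["CU"] == pytest.approx(1.0, rel=0.2)
        assert fit.sigma_b == pytest.approx(0.5, rel=0.3)

    def test_random_intercept_lrt_detects_bird_effect(self):
        df = _toy_lmm_data(seed=2, sigma_b=1.0)
        res = lrt_random_intercept(df, "y", ["x"], [], ["x"],
                                   variance_by=None)
        assert res["lrt"] > 10
        assert res["p"] < 1e-3


class TestEmmeans:
    def test_null_case_all_pairwise_p_one(self):
        # balanced two-method design with identical group means
        rows = []
        for g in range(10):
            m = "IP" if g % 2 else "SC"
            for t in (5.0, 25.0):
                rows.append({"bird_id": f"g{g}", "method": m, "t_air": t,
                             "age": "2cy", "y": 1.0})
        df = pd.DataFrame(rows)
        fit = fit_lmm(df, "y", ["method", "t_air"], ["method", "t_air"], [],
                      variance_by=None)
        out = tr.emmeans_pairwise(fit, "method")
        assert (out["p_adj"] == 1.0).all()

    def test_bonferroni_family_is_table_size(self, default_run):
        contrasts = default_run["stats"]["tb"]["contrasts"]
        m = len(contrasts)
        assert m == 6 * 3     # 4 methods -> 6 pairs, at 3 ambient temperatures
        np.testing.assert_allclose(contrasts["p_adj"],
                                   np.minimum(1.0, contrasts["p"] * m))

    def test_cutaneous_deficit_recovered_within_2_se(self, default_run):
        cfg = default_run["experiment"].config
        contrasts = default_run["stats"]["tb"]["contrasts"]
        at5 = contrasts[contrasts["t_air"] == 5.0]
        cu = at5[at5["contrast"].str.contains("CU")]
        for _, row in cu.iterrows():
            sign = -1.0 if row["contrast"].startswith("CU") else 1.0
            deficit = sign * row["estimate"]
            assert deficit == pytest.approx(cfg.cu_deficit_5,
                                            abs=2 * row["se"] + 0.15)


class TestModelSelection:
    def test_interaction_selected_for_body_temperature(self, default_run):
        aicc_tb = default_run["stats"]["tb"]["aicc"]
        assert aicc_tb.iloc[0]["model"] == "method:t_air"

    def test_no_interaction_selected_for_rmr(self, default_run):
        aicc_rmr = default_run["stats"]["rmr"]["aicc"]
        assert aicc_rmr.iloc[0]["model"] == "no interaction"

    def test_wald_tables_flag_the_generated_effects(self, default_run):
        wald_rmr = default_run["stats"]["rmr"]["wald"].set_index("term")
        assert wald_rmr.loc["t_air", "p"] < 1e-6       # strong cold response
        assert wald_rmr.loc["mass", "p"] < 1e-3        # mass effect
        wald_tb = default_run["stats"]["tb"]["wald"].set_index("term")
        assert wald_tb.loc["method:t_air", "p"] < 1e-6
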