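"""Multivariate FA/life-history association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from handfa.associations import (
    add_bmi_squared,
    fit_multivariate_lm,
    interaction_tests,
    multivariate_block_test,
    pillai_trace_F,
)
from handfa.simulate import RESPONSES, simulate_life_history, simulate_measurements

from conftest import make_covariates_null, small_config


def synthetic_life(n=300, seed=0, fa=None, beta=None, noise=1.0):
    """Life-history frame with known FA effect sizes on standardized scale."""
    rng = np.random.default_rng(seed)
    fa = rng.normal(size=n) if fa is None else np.asarray(fa)
    beta = beta or {}
    df = pd.DataFrame({"individual": [f"I{i:04d}" for i in range(n)]})
    for r in RESPONSES:
        df[r] = beta.get(r, 0.0) * fa + noise * rng.normal(size=n)
    df["education"] = rng.choice(["elementary", "secondary", "university"], n)
    df["cohort"] = rng.choice(["1946-47", "1951-52", "1956-58"], n)
    df["area"] = rng.choice(["North", "South", "West"], n)
    scores = pd.Series(fa, index=df["individual"], name="composite_fa")
    return df, scores


class TestPillai:
    def test_matches_eigenvalue_definition(self):
        # brute force: Pillai = sum of eig(H (H+E)^-1)
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        C = rng.normal(size=(3, 6))
        H = A @ A.T
        E = C @ C.T
        V, F, df1, df2, p = pillai_trace_F(H, E, b=2, df_e=40)
        eig = np.linalg.eigvals(H @ np.linalg.inv(H + E))
        assert V == pytest.approx(float(np.sum(eig.real)), abs=1e-10)
        s, q, b = 2, 3, 2
        m = (abs(q - b) - 1) / 2
        nn = (40 - q - 1) / 2
        assert df1 == s * (2 * m + s + 1)
        assert df2 == s * (2 * nn + s + 1)
        F_ref = (V / s) / (1 - V / s) * (2 * nn + s + 1) / (2 * m + s + 1)
        assert F == pytest.approx(F_ref)
        assert p == pytest.approx(float(stats.f.sf(F_ref, df1, df2)))

    def test_singular_error_sscp_rejected(self):
        H = np.eye(3)
        E = np.zeros((3, 3))
        with pytest.raises(ValueError, match="singular"):
            pillai_trace_F(H, E, b=1, df_e=10)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(9)
        n = 120
        df = pd.DataFrame(
            {
                "g": rng.choice(["a", "b", "c"], n),
                "y1": rng.normal(size=n),
                "y2": rng.normal(size=n),
                "y3": rng.normal(size=n),
            }
        )
        df.loc[df.g == "b", "y1"] += 0.8
        mv = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
        tbl = mv.mv_test().results["g"]["stat"]
        ref_pillai = float(tbl.loc["Pillai's trace", "Value"])
        ref_F = float(tbl.loc["Pillai's trace", "F Value"])
        ref_p = float(tbl.loc["Pillai's trace", "Pr > F"])

        # same model via our machinery
        X = pd.get_dummies(df.g, drop_first=True, dtype=float)
        X.insert(0, "intercept", 1.0)
        Xm = X.to_numpy()
        Y = df[["y1", "y2", "y3"]].to_numpy()
        XtX_inv = np.linalg.inv(Xm.T @ Xm)
        B = XtX_inv @ Xm.T @ Y
        E = (Y - Xm @ B).T @ (Y - Xm @ B)
        idx = [1, 2]
        Lb = B[idx, :]
        G = XtX_inv[np.ix_(idx, idx)]
        H = Lb.T @ np.linalg.solve(G, Lb)
        V, F, df1, df2, p = pillai_trace_F(H, E, b=2, df_e=n - 3)
        assert V == pytest.approx(ref_pillai, abs=1e-8)
        assert F == pytest.approx(ref_F, rel=1e-6)
        assert p == pytest.approx(ref_p, abs=1e-8)


class TestBmiSquared:
    def test_values(self):
        life = pd.DataFrame({"bmi": [26.4, 7.0, np.nan]})
        out = add_bmi_squared(life)
        assert out.bmi_squared[0] == pytest.approx(696.96)
        assert out.bmi_squared[1] == pytest.approx(49.0)
        assert np.isnan(out.bmi_squared[2])

    def test_missing_bmi_rejected(self):
        with pytest.raises(ValueError, match="bmi"):
            add_bmi_squared(pd.DataFrame({"x": [1.0]}))


class TestFit:
    def test_recovers_known_standardized_beta(self):
        # noiseless-ish: response = 0.5 * fa + small noise, all z-scored
        life, scores = synthetic_life(
            n=2000, seed=1, beta={"bmi": 0.5}, noise=np.sqrt(1 - 0.25)
        )
        res = fit_multivariate_lm(life, scores)
        row = res.per_response.set_index("response").loc["bmi"]
        assert row.beta == pytest.approx(0.5, abs=0.06)
        assert row.p < 1e-10

    def test_exactly_linear_response(self):
        life, scores = synthetic_life(n=200, seed=2)
        life["bmi"] = 0.5 * scores.to_numpy()  # perfectly collinear with FA
        res = fit_multivariate_lm(life, scores)
        row = res.per_response.set_index("response").loc["bmi"]
        # z-scored response on z-scored fa: slope is exactly 1
        assert row.beta == pytest.approx(1.0, abs=1e-10)

    def test_t_squared_equals_univariate_f(self):
        life, scores = synthetic_life(n=150, seed=3, beta={"n_offspring": 0.3})
        res = fit_multivariate_lm(life, scores, responses=["n_offspring"])
        row = res.per_response.iloc[0]
        block = res.block_tests.set_index("block").loc["fa"]
        assert block.F == pytest.approx(row.t**2, rel=1e-9)
        assert block.p == pytest.approx(row.p, rel=1e-9)

    def test_reference_level_invariance(self):
        life, scores = synthetic_life(n=250, seed=4, beta={"bmi": 0.2})
        res_a = fit_multivariate_lm(life, scores)
        relabel = {"elementary": "z_elementary"}  # changes dummy reference
        life2 = life.assign(education=life.education.replace(relabel))
        res_b = fit_multivariate_lm(life2, scores)
        pd.testing.assert_frame_equal(
            res_a.per_response, res_b.per_response, atol=1e-10, rtol=0
        )
        fa_a = res_a.block_tests.set_index("block").loc["fa"]
        fa_b = res_b.block_tests.set_index("block").loc["fa"]
        assert fa_a.p == pytest.approx(fa_b.p, abs=1e-12)
        ed_a = res_a.block_tests.set_index("block").loc["education"]
        ed_b = res_b.block_tests.set_index("block").loc["education"]
        assert ed_a.p == pytest.approx(ed_b.p, abs=1e-12)

    def test_single_level_covariate_rejected(self):
        life, scores = synthetic_life(n=100, seed=5)
        life["area"] = "North"
        with pytest.raises(ValueError, match="single level"):
            fit_multivariate_lm(life, scores)

    def test_rank_deficiency_names_columns(self):
        life, scores = synthetic_life(n=100, seed=6)
        life["cohort"] = life["education"].map(
            {"elementary": "1946-47", "secondary": "1951-52", "university": "1956-58"}
        )  # cohort dummies collinear with education dummies
        with pytest.raises(ValueError, match="rank deficient"):
            fit_multivariate_lm(life, scores)

    def test_too_few_complete_cases_rejected(self):
        life, scores = synthetic_life(n=20, seed=7)
        with pytest.raises(ValueError, match="complete cases"):
            fit_multivariate_lm(life, scores)

    def test_unknown_block_rejected(self):
        life, scores = synthetic_life(n=100, seed=8)
        res = fit_multivariate_lm(life, scores)
        with pytest.raises(ValueError, match="no design columns"):
            multivariate_block_test(res, "nope")

    def test_bmi_squared_added_as_response(self):
        life, scores = synthetic_life(n=150, seed=9)
        res = fit_multivariate_lm(life, scores, bmi_squared=True)
        assert "bmi_squared" in res.responses
        assert len(res.responses) == len(RESPONSES) + 1


class TestInteraction:
    def test_detects_constructed_slope_heterogeneity(self):
        # cohort-specific slopes +0.5 / 0 / -0.5 on bmi
        rng = np.random.default_rng(11)
        n = 2000
        fa = rng.normal(size=n)
        cohort = rng.choice(["1946-47", "1951-52", "1956-58"], n)
        slope = np.select(
            [cohort == "1946-47", cohort == "1951-52"], [0.5, 0.0], default=-0.5
        )
        life, scores = synthetic_life(n=n, seed=12, fa=fa)
        life["cohort"] = cohort
        life["bmi"] = slope * fa + rng.normal(size=n)
        res = interaction_tests(life, scores, factor="cohort")
        assert res.block == "fa_x_cohort"
        assert res.p < 0.001

    def test_invalid_factor_rejected(self):
        life, scores = synthetic_life(n=100, seed=13)
        with pytest.raises(ValueError, match="cohort"):
            interaction_tests(life, scores, factor="area")

    def test_null_interaction_p_uniform(self):
        # under the null the interaction p-values should be ~Uniform(0,1)
        ps = []
        for seed in range(300):
            life, scores = synthetic_life(n=120, seed=1000 + seed)
            ps.append(interaction_tests(life, scores, factor="education").p)
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.001


class TestFullPath:
    def test_null_cohort_fa_block_not_extreme(self):
        # study-style generator with zero life-history effects: the FA block
        # p-value is a single draw; just require it is a valid probability and
        # the bookkeeping (df, n) is consistent
        cfg = small_config(n=209, n_sessions=2, n_traits=5)
        cfg.covariate_levels = make_covariates_null()
        meas, truth = simulate_measurements(cfg, seed=31)
        life = simulate_life_history(cfg, truth, seed=32)

        from handfa.composite import composite_fa
        from handfa.fa_model import SignedFAEstimates, fit_all_traits

        _, _, _, signed = fit_all_traits(meas)
        comp = composite_fa(SignedFAEstimates(table=signed))
        res = fit_multivariate_lm(life, comp)
        fa_row = res.block_tests.set_index("block").loc["fa"]
        assert 0.0 <= fa_row.p <= 1.0
        assert res.n_complete <= 209
        assert fa_row.df1 == len(res.responses)
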