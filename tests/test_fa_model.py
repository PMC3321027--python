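"""Mixed-model decomposition: REML components, DA and real-FA tests, BLUPs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handfa.fa_model import (
    FAFit,
    fit_fa_model,
    restricted_loglik,
    signed_fa,
    summarize_traits,
)
from handfa.fa_model import test_directional_asymmetry as da_test
from handfa.fa_model import test_real_fa as real_fa_test

from conftest import bilateral_frame


def constant_frame(n=5, K=2, c=4.2):
    rows = []
    for i in range(n):
        for side in ("L", "R"):
            for k in range(1, K + 1):
                rows.append((f"I{i}", side, k, "T", c))
    return pd.DataFrame(rows, columns=["individual", "side", "session", "trait", "value"])


class TestFit:
    def test_constant_data_degenerates_to_zero_components(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            fit = fit_fa_model(constant_frame(c=4.2))
        assert fit.mu_hat == 4.2
        assert fit.delta_hat == 0.0
        assert fit.sigma_ind == fit.sigma_fa == fit.sigma_me == 0.0

    def test_pure_da_recovered_exactly(self):
        n = 20
        left = np.linspace(5, 6, n)
        frames = [
            pd.DataFrame({"individual": [f"I{i}" for i in range(n)], "side": "L",
                          "session": 1, "trait": "T", "value": left}),
            pd.DataFrame({"individual": [f"I{i}" for i in range(n)], "side": "R",
                          "session": 1, "trait": "T", "value": left + 0.3}),
        ]
        fit = fit_fa_model(pd.concat(frames, ignore_index=True))
        assert fit.delta_hat == pytest.approx(0.3)
        assert fit.sigma_fa == 0.0
        assert fit.sigma_me == 0.0
        assert fit.sigma_ind > 0

    def test_balanced_delta_is_mean_side_difference(self):
        df = bilateral_frame(n=60, seed=14)
        fit = fit_fa_model(df)
        wide = df.pivot_table(index="individual", columns="side", values="value")
        assert fit.delta_hat == pytest.approx(float((wide["R"] - wide["L"]).mean()))

    def test_one_sided_trait_rejected(self):
        df = bilateral_frame(n=10, seed=0)
        with pytest.raises(ValueError, match="one side"):
            fit_fa_model(df[df.side == "L"])

    def test_session_relabeling_leaves_delta_unchanged(self):
        df = bilateral_frame(n=40, K=2, seed=3)
        swapped = df.assign(session=3 - df.session)
        assert fit_fa_model(df).delta_hat == pytest.approx(
            fit_fa_model(swapped).delta_hat, abs=1e-12
        )

    def test_matches_statsmodels_mixedlm(self):
        # independent cross-check: variance-components MixedLM on an
        # interior-optimum dataset
        import statsmodels.formula.api as smf

        df = bilateral_frame(n=150, K=2, seed=5).assign(
            x=lambda d: np.where(d.side == "R", 0.5, -0.5)
        )
        fit = fit_fa_model(df)
        sm = smf.mixedlm(
            "value ~ x", df, groups="individual", re_formula="1",
            vc_formula={"slope": "0 + x"},
        ).fit(reml=True, method="lbfgs")
        assert fit.delta_hat == pytest.approx(sm.params["x"], abs=1e-5)
        assert fit.sigma_ind**2 == pytest.approx(float(sm.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma_fa**2 == pytest.approx(float(sm.vcomp[0]), rel=1e-3)
        assert fit.sigma_me**2 == pytest.approx(float(sm.scale), rel=1e-3)


class TestRestrictedLoglik:
    def test_translation_invariance(self):
        df = bilateral_frame(n=25, seed=8)
        theta = (0.2, 0.01, 0.001)
        shifted = df.assign(value=df.value + 100.0)
        assert restricted_loglik(theta, df) == pytest.approx(
            restricted_loglik(theta, shifted), abs=1e-6
        )

    def test_negative_component_rejected(self):
        df = bilateral_frame(n=10, seed=0)
        with pytest.raises(ValueError, match="nonnegative"):
            restricted_loglik((-0.1, 0.1, 0.1), df)

    def test_matches_dense_matrix_oracle(self):
        # 3 individuals: build the full 12x12 marginal covariance explicitly
        # and evaluate the REML objective with raw linear algebra
        df = bilateral_frame(n=3, K=2, seed=12)
        theta = (0.3, 0.02, 0.005)
        s2i, s2f, s2m = theta

        df_s = df.sort_values(["individual", "side", "session"]).reset_index(drop=True)
        y = df_s.value.to_numpy()
        x = np.where(df_s.side == "R", 0.5, -0.5)
        ind = pd.factorize(df_s.individual)[0]
        n = len(y)
        Z_ind = (ind[:, None] == np.arange(3)[None, :]).astype(float)
        Z_fa = Z_ind * x[:, None]
        V = s2i * Z_ind @ Z_ind.T + s2f * Z_fa @ Z_fa.T + s2m * np.eye(n)
        X = np.column_stack([np.ones(n), x])
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        ll_ref = -0.5 * (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            + r @ Vi @ r
            + (n - 2) * np.log(2 * np.pi)
        )
        assert restricted_loglik(theta, df) == pytest.approx(ll_ref, abs=1e-8)

    def test_fit_is_local_optimum_of_objective(self):
        df = bilateral_frame(n=50, seed=2)
        fit = fit_fa_model(df)
        theta = np.array([fit.sigma_ind**2, fit.sigma_fa**2, fit.sigma_me**2])
        base = restricted_loglik(tuple(theta), df)
        for j in range(3):
            for sign in (-1, 1):
                probe = theta.copy()
                probe[j] = max(probe[j] + sign * 1e-3 * max(theta[j], 1e-4), 0.0)
                assert restricted_loglik(tuple(probe), df) <= base + 1e-9


class TestDATest:
    def test_side_symmetric_data_gives_zero_statistic(self):
        n = 15
        vals = np.linspace(3, 4, n)
        df = pd.concat(
            [
                pd.DataFrame({"individual": [f"I{i}" for i in range(n)], "side": "L",
                              "session": 1, "trait": "T", "value": vals}),
                pd.DataFrame({"individual": [f"I{i}" for i in range(n)], "side": "R",
                              "session": 1, "trait": "T", "value": vals}),
            ],
            ignore_index=True,
        )
        res = da_test(df)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_power_at_study_effect_size(self):
        # delta = 0.08 with sigma_fa = 0.10, sigma_me = 0.03, n = 200:
        # the DA test should nearly always reject
        hits = 0
        reps = 500
        for r in range(reps):
            df = bilateral_frame(n=200, K=2, delta=0.08, sigma_fa=0.10,
                                 sigma_me=0.03, seed=10_000 + r)
            if da_test(df).p < 0.05:
                hits += 1
        assert hits / reps > 0.9


class TestRealFA:
    def test_single_session_rejected(self):
        df = bilateral_frame(n=20, K=1, seed=4)
        with pytest.raises(ValueError, match="confounded"):
            real_fa_test(df)

    def test_strong_fa_signal_detected(self):
        df = bilateral_frame(n=200, K=2, sigma_fa=0.1, sigma_me=0.01, seed=6)
        res = real_fa_test(df)
        assert res.p < 1e-6

    def test_null_fa_rejection_rate_conservative(self):
        # sigma_fa = 0: the boundary mixture test should reject at most ~5%
        reps, hits = 200, 0
        for r in range(reps):
            df = bilateral_frame(n=80, K=2, delta=0.0, sigma_fa=0.0,
                                 sigma_me=0.05, seed=20_000 + r)
            if real_fa_test(df).p < 0.05:
                hits += 1
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestSignedFA:
    def test_blup_never_exceeds_raw(self):
        df = bilateral_frame(n=80, seed=7)
        fit = fit_fa_model(df)
        est = signed_fa(fit, df)
        assert (est.table.blup.abs() <= est.table.raw.abs() + 1e-12).all()

    def test_zero_me_gives_no_shrinkage(self):
        df = bilateral_frame(n=30, K=1, sigma_me=0.0, seed=9)
        fit = fit_fa_model(df)
        assert fit.sigma_me == 0.0
        est = signed_fa(fit, df)
        np.testing.assert_allclose(est.table.blup, est.table.raw)

    def test_zero_fa_variance_gives_full_shrinkage(self):
        df = bilateral_frame(n=40, seed=10)
        fit = fit_fa_model(df)
        fit0 = FAFit(
            trait_id=fit.trait_id, mu_hat=fit.mu_hat, delta_hat=fit.delta_hat,
            sigma_ind=fit.sigma_ind, sigma_fa=0.0, sigma_me=fit.sigma_me,
            reml_loglik=fit.reml_loglik, n_individuals=fit.n_individuals,
        )
        est = signed_fa(fit0, df)
        assert (est.table.blup == 0.0).all()

    def test_missing_side_gives_no_estimate(self):
        df = bilateral_frame(n=30, seed=11)
        dropped = df[~((df.individual == "I00000") & (df.side == "R"))]
        fit = fit_fa_model(dropped)
        est = signed_fa(fit, dropped)
        assert "I00000" not in set(est.table.individual)
        assert len(est.table) == 29

    def test_raw_mean_is_centred_on_zero(self):
        df = bilateral_frame(n=100, seed=13)
        fit = fit_fa_model(df)
        est = signed_fa(fit, df)
        # DA-corrected: raw values average to ~0 by construction
        assert est.table.raw.mean() == pytest.approx(0.0, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_blup_sign_matches_raw(self, seed):
        df = bilateral_frame(n=25, seed=seed)
        fit = fit_fa_model(df)
        est = signed_fa(fit, df)
        assert (np.sign(est.table.blup) == np.sign(est.table.raw)).all() or (
            est.table.blup == 0
        ).all()


class TestSummary:
    def test_empty_input_gives_empty_table(self):
        out = summarize_traits([])
        assert len(out) == 0
        assert "real_fa" in out.columns

    def test_percent_of_size_arithmetic(self):
        fit = FAFit("T", mu_hat=8.0, delta_hat=0.08, sigma_ind=1, sigma_fa=0.1,
                    sigma_me=0.01, reml_loglik=0.0, n_individuals=10)
        out = summarize_traits([fit])
        assert out.da_percent_of_size.iloc[0] == pytest.approx(1.0)

    def test_misaligned_inputs_rejected(self):
        fit = FAFit("T", 8.0, 0.0, 1, 0.1, 0.01, 0.0, 10)
        with pytest.raises(ValueError, match="aligned"):
            summarize_traits([fit], da_tests=[])

    def test_cohort_summary_has_21_rows(self, cohort_fits):
        fits, da_tests, _, _ = cohort_fits
        out = summarize_traits(fits, da_tests)
        assert len(out) == 21
        assert set(out.trait) == set(
            ["P"] + [f"D{d}" for d in (2, 3, 4, 5)]
            + [f"D{d}{p}" for d in (2, 3, 4, 5) for p in (1, 2, 3)]
            + [f"W{d}" for d in (2, 3, 4, 5)]
        )
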