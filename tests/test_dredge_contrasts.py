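"""Exhaustive AIC model selection and post-hoc contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from whalecues.stats import dredge_aic, fit_poisson_glm, posthoc_contrasts


def _ols_fitter(formula: str, data: pd.DataFrame):
    return smf.ols(formula, data).fit()


@pytest.fixture(scope="module")
def lm_data():
    rng = np.random.default_rng(0)
    n = 200
    df = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "x3": rng.normal(size=n),
    })
    df["y"] = 1.0 + 2.0 * df.x1 + rng.normal(0, 1.0, n)
    return df


class TestDredge:
    def test_fits_every_subset(self, lm_data):
        table = dredge_aic(lm_data, "y", ["x1", "x2", "x3"], _ols_fitter)
        assert len(table) == 2**3
        assert (table["error"] == "").all()
        assert table["delta_aic"].iloc[0] == 0.0
        assert table["delta_aic"].is_monotonic_increasing

    def test_strong_predictor_always_selected(self, lm_data):
        table = dredge_aic(lm_data, "y", ["x1", "x2", "x3"], _ols_fitter)
        assert table.loc[0, "x1"]  # the real effect is in the best model

    def test_gaussian_aic_closed_form(self, lm_data):
        """AIC of each OLS fit equals n ln(RSS/n) + n + n ln(2 pi) + 2k."""
        table = dredge_aic(lm_data, "y", ["x1", "x2"], _ols_fitter)
        n = len(lm_data)
        for _, row in table.iterrows():
            fit = smf.ols(row["formula"], lm_data).fit()
            rss = float(fit.ssr)
            k = fit.df_model + 1
            expected = n * np.log(rss / n) + n + n * np.log(2 * np.pi) + 2 * k
            assert row["aic"] == pytest.approx(expected, abs=1e-8)

    def test_affine_recoding_does_not_change_ranking(self, lm_data):
        recoded = lm_data.copy()
        recoded["x1"] = 3.0 * recoded["x1"] + 7.0
        t1 = dredge_aic(lm_data, "y", ["x1", "x2"], _ols_fitter)
        t2 = dredge_aic(recoded, "y", ["x1", "x2"], _ols_fitter)
        order1 = [tuple(r[p] for p in ("x1", "x2")) for _, r in t1.iterrows()]
        order2 = [tuple(r[p] for p in ("x1", "x2")) for _, r in t2.iterrows()]
        assert order1 == order2

    def test_failed_fits_recorded_not_dropped(self, lm_data):
        def flaky(formula, data):
            if "x2" in formula:
                raise RuntimeError("boom")
            return _ols_fitter(formula, data)

        table = dredge_aic(lm_data, "y", ["x1", "x2"], flaky)
        assert len(table) == 4
        assert (table["error"] != "").sum() == 2

    def test_too_many_predictors_rejected(self, lm_data):
        with pytest.raises(ValueError, match="12"):
            dredge_aic(lm_data, "y", [f"p{i}" for i in range(13)], _ols_fitter)

    def test_selection_consistency_under_replication(self):
        """Strong (5 SE) vs pure-noise predictor: the dredge keeps the strong one."""
        rng = np.random.default_rng(1)
        hits = 0
        reps = 60
        for _ in range(reps):
            n = 100
            df = pd.DataFrame({"x_sig": rng.normal(size=n), "x_noise": rng.normal(size=n)})
            df["y"] = 0.5 * df["x_sig"] + rng.normal(0, 1.0, n)  # |beta|/SE ~ 5
            table = dredge_aic(df, "y", ["x_sig", "x_noise"], _ols_fitter)
            hits += bool(table.loc[0, "x_sig"])
        assert hits / reps >= 0.95


class TestContrasts:
    @pytest.fixture(scope="class")
    def poisson_fit(self):
        rng = np.random.default_rng(2)
        g = np.repeat([0, 1, 2], 100)
        X = np.column_stack([np.ones(300), g == 1, g == 2]).astype(float)
        counts = rng.poisson(np.exp(X @ [0.5, 0.8, -0.2]))
        return fit_poisson_glm(counts, X)

    def test_identity_contrast_reproduces_wald_z(self, poisson_fit):
        out = posthoc_contrasts(poisson_fit, np.eye(3))
        z_direct = (poisson_fit.params / poisson_fit.bse).to_numpy()
        np.testing.assert_allclose(out["z"], z_direct, atol=1e-10)
        np.testing.assert_allclose(out["p_raw"], poisson_fit.pvalues, atol=1e-10)

    def test_bonferroni_doubles_with_two_contrasts(self, poisson_fit):
        C = np.array([[0, 1, 0], [0, 0, 1]], dtype=float)
        out = posthoc_contrasts(poisson_fit, C)
        np.testing.assert_allclose(
            out["p_adj"], np.minimum(1.0, 2 * out["p_raw"]), atol=1e-12
        )

    def test_single_step_between_raw_and_bonferroni(self, poisson_fit):
        C = np.array([[0, 1, 0], [0, 0, 1], [1, 1, -1]], dtype=float)
        out = posthoc_contrasts(poisson_fit, C, method="single-step")
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        bonf = np.minimum(1.0, 3 * out["p_raw"])
        assert (out["p_adj"] <= bonf + 0.01).all()

    def test_rank_deficient_contrasts_rejected(self, poisson_fit):
        C = np.array([[0, 1, 0], [0, 2, 0]], dtype=float)
        with pytest.raises(ValueError, match="rank"):
            posthoc_contrasts(poisson_fit, C)

    def test_familywise_error_controlled_under_null(self):
        """1000 null replicates, 4 contrasts: FWER stays below ~0.06."""
        rng = np.random.default_rng(3)
        n, reps = 120, 1000
        rejections = 0
        C = np.eye(4)
        for _ in range(reps):
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = rng.normal(size=n)  # all true coefficients zero
            fit = sm.OLS(y, X).fit()
            out = posthoc_contrasts(fit, C)
            rejections += bool((out["p_adj"] < 0.05).any())
        assert rejections / reps <= 0.06


def test_contrast_shape_mismatch_rejected():
    rng = np.random.default_rng(4)
    fit = sm.OLS(rng.normal(size=50), np.ones((50, 1))).fit()
    with pytest.raises(ValueError, match="columns"):
        posthoc_contrasts(fit, np.eye(3))
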