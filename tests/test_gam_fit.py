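"""Penalized Gamma GAM fitting: equivalences, limits, inference, oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from pondn2o.gam import (
    GamSpecification,
    SmoothTerm,
    build_design,
    deviance_explained,
    fit_gam,
    gamma_deviance,
    n2o_gam_specification,
)

import oracles


def one_smooth_data(seed=42, n=120):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    y = rng.gamma(8.0, np.exp(1.0 + np.sin(2 * np.pi * x)) / 8.0)
    return pd.DataFrame({"n2o_nm": y, "x": x})


def one_smooth_spec(double_penalty=False):
    return GamSpecification(
        smooths=(SmoothTerm("s(x)", ("x",), "thin_plate", 9),),
        double_penalty=double_penalty,
    )


class TestEquivalences:
    def test_unpenalized_matches_glm(self):
        """With the penalty switched off the P-IRLS fit reproduces an
        unpenalized Gamma(log) GLM on the same basis columns."""
        import statsmodels.api as sm

        tab = one_smooth_data()
        design = build_design(tab, one_smooth_spec())
        fit = fit_gam(design, fixed_log_lambda=np.array([-np.inf]))
        glm = sm.GLM(
            design.y, design.X, family=sm.families.Gamma(sm.families.links.Log())
        ).fit(tol=1e-13, maxiter=1000)
        assert np.abs(fit.beta - glm.params).max() < 1e-8

    def test_intercept_only_zero_deviance_explained(self):
        tab = one_smooth_data()
        spec = GamSpecification(smooths=(), double_penalty=False)
        fit = fit_gam(tab, spec)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-12)
        assert fit.fitted == pytest.approx(np.full(len(tab), tab.n2o_nm.mean()))

    def test_infinite_penalty_approaches_intercept_only(self):
        """With the double penalty and huge smoothing parameters every
        smooth's EDF collapses and the fit approaches the null model."""
        tab = one_smooth_data()
        design = build_design(tab, one_smooth_spec(double_penalty=True))
        fit = fit_gam(design, fixed_log_lambda=np.array([20.0, 20.0]))
        assert fit.edf_by_term["s(x)"] < 1e-4
        assert np.ptp(fit.fitted) < 1e-3 * tab.n2o_nm.mean()

    def test_deviance_formula_matches_oracle(self, rng):
        y = rng.gamma(4.0, 3.0, 60)
        mu = y * rng.uniform(0.7, 1.4, 60)
        assert gamma_deviance(y, mu) == pytest.approx(
            oracles.gamma_deviance_direct(y, mu), abs=1e-10
        )

    def test_mgcv_cross_check(self, tmp_path):
        """Independent penalized-REML oracle: mgcv with shrinkage selection
        on the same data agrees on fit quality and fitted values."""
        rng = np.random.default_rng(11)
        n = 200
        x0, x1 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        eta = 1.0 + np.sin(2 * np.pi * x0) + 3.2 * (x1 - 0.5) ** 2
        y = rng.gamma(6.0, np.exp(eta) / 6.0)
        tab = pd.DataFrame({"n2o_nm": y, "x0": x0, "x1": x1})
        spec = GamSpecification(
            smooths=(
                SmoothTerm("s(x0)", ("x0",), "thin_plate", 9),
                SmoothTerm("s(x1)", ("x1",), "thin_plate", 9),
            ),
            double_penalty=True,
        )
        fit = fit_gam(tab, spec)
        csv = tmp_path / "data.csv"
        out = tmp_path / "fit.csv"
        tab.to_csv(csv, index=False)
        script = (
            f'library(mgcv); d <- read.csv("{csv}");'
            'm <- gam(n2o_nm ~ s(x0,k=10)+s(x1,k=10), family=Gamma(link="log"),'
            'data=d, method="REML", select=TRUE);'
            'cat(summary(m)$dev.expl, "\\n");'
            f'write.csv(data.frame(mu=fitted(m)), "{out}", row.names=FALSE)'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        dev_expl_r = float(proc.stdout.strip().split()[-1])
        mu_r = pd.read_csv(out)["mu"].to_numpy()
        assert abs(fit.deviance_explained - dev_expl_r) < 0.03
        assert np.corrcoef(fit.fitted, mu_r)[0, 1] > 0.99


@pytest.fixture(scope="module")
def recovery_fit():
    """Gamma data from two known smooths plus one null covariate."""
    rng = np.random.default_rng(5)
    n = 250
    x0, x1, x2 = (rng.uniform(0, 1, n) for _ in range(3))
    truth0 = 2.0 * np.sin(np.pi * x0)
    truth1 = 2.0 * (x1 - 0.5) ** 2 * 4
    y = rng.gamma(8.0, np.exp(1.0 + truth0 + truth1) / 8.0)
    tab = pd.DataFrame({"n2o_nm": y, "x0": x0, "x1": x1, "x2": x2})
    spec = GamSpecification(
        smooths=tuple(
            SmoothTerm(f"s(x{i})", (f"x{i}",), "thin_plate", 9) for i in range(3)
        ),
        double_penalty=True,
    )
    return fit_gam(tab, spec), (truth0, truth1), tab


class TestInference:
    def test_partial_effects_decompose_linear_predictor(self, recovery_fit):
        fit, _, _ = recovery_fit
        eta = np.full(fit.design.n, fit.beta[0])
        for t in fit.design.terms:
            eta = eta + fit.design.X[:, t.sl] @ fit.beta[t.sl]
        assert np.abs(eta - fit.linear_predictor).max() < 1e-8

    def test_shrunk_term_has_flat_partial_effect(self, recovery_fit):
        fit, _, _ = recovery_fit
        if fit.edf_by_term["s(x2)"] < 0.01:
            pe = fit.partial_effect("s(x2)", grid=50)
            assert np.max(np.abs(pe.effect)) < 1e-3

    def test_intervals_cover_truth_mostly(self, recovery_fit):
        fit, (truth0, _), tab = recovery_fit
        pe = fit.partial_effect("s(x0)", grid={"x0": tab.x0.to_numpy()})
        centred = truth0 - truth0.mean()
        inside = (centred >= pe.lower) & (centred <= pe.upper)
        assert inside.mean() > 0.7  # pointwise 95% bands, approximate

    def test_extrapolation_flagged(self, recovery_fit):
        fit, _, _ = recovery_fit
        pe = fit.partial_effect("s(x0)", grid={"x0": np.array([0.5, 2.5])})
        assert pe.extrapolated.tolist() == [False, True]

    def test_reml_history_monotone_nonincreasing(self, recovery_fit):
        fit, _, _ = recovery_fit
        hist = np.array(fit.reml_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-6 * (np.abs(hist[:-1]) + 1))

    def test_pvalues_reported_for_all_terms(self, recovery_fit):
        fit, _, _ = recovery_fit
        pvals = fit.approximate_pvalues()
        assert set(pvals) == {"s(x0)", "s(x1)", "s(x2)"}
        assert all(0.0 <= p <= 1.0 for p in pvals.values())
        assert pvals["s(x0)"] < 0.01  # strong true effect

    def test_prediction_invariant_to_covariate_rescaling(self, recovery_fit):
        fit, _, tab = recovery_fit
        scaled = tab.copy()
        scaled["x0"] = 1000.0 * scaled["x0"] - 37.0
        spec = GamSpecification(
            smooths=tuple(
                SmoothTerm(f"s(x{i})", (f"x{i}",), "thin_plate", 9) for i in range(3)
            ),
            double_penalty=True,
        )
        refit = fit_gam(scaled, spec)
        assert np.corrcoef(refit.fitted, fit.fitted)[0, 1] > 0.999


class TestSurveyModel:
    def test_tensor_surface_matches_planted_interaction(self):
        """On the synthetic survey the fitted tensor surface predicts more
        N2O at (unstratified, high DIN) than at (stratified, high DIN)."""
        from pondn2o.gam import transform_covariates
        from pondn2o.synthetic import SurveyGeneratorConfig, generate_survey

        records, truth = generate_survey(SurveyGeneratorConfig(seed=4))
        tab = transform_covariates(records)
        fit = fit_gam(tab, n2o_gam_specification(random_intercept=False))
        hi_din = np.log(6000.0)
        low_bf = fit.predict(
            _grid_row(tab, sqrt_bf=0.0, log_din=hi_din), response_scale=False
        )
        high_bf = fit.predict(
            _grid_row(tab, sqrt_bf=0.19, log_din=hi_din), response_scale=False
        )
        assert low_bf[0] > high_bf[0]

    def test_null_deviance_zero_errors(self):
        tab = pd.DataFrame({"n2o_nm": [3.0, 3.0, 3.0, 3.0], "x": [1.0, 2.0, 3.0, 4.0]})
        spec = GamSpecification(smooths=(), double_penalty=False)
        fit = fit_gam(tab, spec)
        with pytest.raises(ValueError):
            deviance_explained(fit)


def _grid_row(tab, **overrides):
    num = tab.select_dtypes("number")
    row = {c: [num[c].median()] for c in num.columns if c != "n2o_nm"}
    row["site_id"] = ["new"]
    for k, v in overrides.items():
        row[k] = [v]
    return pd.DataFrame(row)
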