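"""Spline bases, penalties, transformations and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from pondn2o.gam import (
    CubicRegressionSpline,
    GamSpecification,
    SmoothTerm,
    ThinPlateSpline,
    build_design,
    screen_collinearity,
    transform_covariates,
)
from pondn2o.gam.bases import (
    RandomIntercept,
    TensorProduct,
    penalty_nullspace_projector,
    sum_to_zero_nullspace,
)
from pondn2o.gam.model import SiteRecord


@pytest.fixture
def x(rng):
    return rng.uniform(0.0, 10.0, 80)


class TestCubicRegressionSpline:
    def test_penalty_annihilates_linear_functions(self, x):
        """The curvature penalty's null space contains straight lines:
        coefficients that are knot values of a line give zero penalty."""
        crs = CubicRegressionSpline(x, 6)
        beta = 2.0 + 0.7 * crs.knots
        assert beta @ crs.S @ beta == pytest.approx(0.0, abs=1e-10)

    def test_interpolates_knot_values(self, x):
        crs = CubicRegressionSpline(x, 6)
        X = crs.matrix(crs.knots)
        assert np.allclose(X, np.eye(6), atol=1e-10)

    def test_basis_size_exceeding_distinct_values_errors(self):
        with pytest.raises(ValueError, match="smaller basis"):
            CubicRegressionSpline(np.array([1.0, 2.0, 3.0]), 5)


class TestThinPlateSpline:
    def test_penalty_psd_and_null_dimension(self, x, rng):
        for k in (5, 8, 10):
            tps = ThinPlateSpline(rng.uniform(0, 1, 60), k)
            S = tps.penalties()[0]
            vals = np.linalg.eigvalsh(S)
            assert vals.min() > -1e-8 * max(vals.max(), 1.0)  # PSD
            # polynomial null space {1, x} carried as unpenalized columns
            assert np.sum(vals < 1e-10 * vals.max()) == 2

    def test_reproduces_linear_functions_exactly(self, x):
        tps = ThinPlateSpline(x, 8)
        X = tps.matrix(x)
        # last two columns are the polynomial part [1, x_scaled]
        coef = np.zeros(8)
        coef[-2:] = [1.0, 2.0]
        u = (x - x.min()) / (x.max() - x.min())
        assert np.allclose(X @ coef, 1.0 + 2.0 * u, atol=1e-10)


class TestTensorAndRandom:
    def test_tensor_shapes_and_penalties(self, rng):
        x1, x2 = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        te = TensorProduct(x1, x2, 4, 4)
        X = te.matrix(x1, x2)
        assert X.shape == (50, 16)
        for S in te.penalties():
            assert S.shape == (16, 16)
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > -1e-8

    def test_random_intercept_indicators(self):
        ri = RandomIntercept.from_values(["a", "b", "a", "c"])
        X = ri.matrix(["a", "b", "a", "c", "zzz"])
        assert X.shape == (5, 3)
        assert X[:4].sum() == 4.0
        assert X[4].sum() == 0.0  # unseen level maps to population mean


class TestConstraintsAndAssembly:
    def test_sum_to_zero_constraint(self, rng):
        X = rng.normal(size=(40, 7))
        Z = sum_to_zero_nullspace(X)
        assert np.allclose((X @ Z).sum(axis=0), 0.0, atol=1e-9)

    def test_penalty_nullspace_projector(self, rng):
        A = rng.normal(size=(6, 4))
        S = A @ A.T  # rank 4, null dim 2
        P = penalty_nullspace_projector(S)
        assert P.shape == (6, 6)
        assert np.allclose(P @ P, P, atol=1e-8)  # projector
        assert np.allclose(S @ P, 0.0, atol=1e-6)

    def test_design_columns_sum_to_zero_and_penalties_psd(self, rng):
        n = 90
        tab = pd.DataFrame(
            {
                "n2o_nm": rng.gamma(5, 2, n),
                "a": rng.uniform(0, 1, n),
                "b": rng.uniform(0, 1, n),
            }
        )
        spec = GamSpecification(
            smooths=(
                SmoothTerm("s(a)", ("a",), "thin_plate", 9),
                SmoothTerm("te(a,b)", ("a", "b"), "tensor_product"),
            ),
            double_penalty=True,
        )
        design = build_design(tab, spec)
        assert design.X.shape[1] == 1 + 9 + 15  # intercept + smooth + tensor
        for t in design.terms:
            assert np.allclose(design.X[:, t.sl].sum(axis=0), 0.0, atol=1e-8)
        for blk in design.penalties:
            vals = np.linalg.eigvalsh(blk.S)
            assert np.allclose(blk.S, blk.S.T)
            assert vals.min() > -1e-8 * max(vals.max(), 1.0)
        kinds = [(b.term, b.kind) for b in design.penalties]
        assert ("s(a)", "null") in kinds  # double penalty present
        assert sum(1 for t, k in kinds if t == "te(a,b)" and k == "range") == 2


class TestTransforms:
    def make_record(self, **kw):
        base = dict(
            site_id="s", n2o_nm=5.0, surf_do=100.0, deep_do=50.0, sed_cn=10.0,
            chla=np.e, surf_ph=8.0, n_to_p=20.0, bf_max=0.0, din=32.0,
        )
        base.update(kw)
        return SiteRecord(**base)

    def test_log_and_sqrt_columns(self):
        table = transform_covariates([self.make_record()])
        assert table["log_chla"].iloc[0] == pytest.approx(1.0)
        assert table["sqrt_bf"].iloc[0] == 0.0
        assert table["surf_do"].iloc[0] == 100.0

    def test_survey_range_endpoints(self):
        lo = transform_covariates([self.make_record(din=32.0)])["log_din"].iloc[0]
        hi = transform_covariates([self.make_record(din=7688.0)])["log_din"].iloc[0]
        assert lo == pytest.approx(np.log(32.0), rel=1e-12)
        assert hi == pytest.approx(np.log(7688.0), rel=1e-12)

    def test_nonpositive_log_field_names_site(self):
        df = pd.DataFrame([vars(self.make_record())])
        df.loc[0, "chla"] = -1.0
        with pytest.raises(ValueError, match="site s.*chla"):
            transform_covariates(df)

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="n2o"):
            self.make_record(n2o_nm=0.0)
        with pytest.raises(ValueError, match="din"):
            self.make_record(din=0.0)


class TestCollinearityScreen:
    def test_duplicate_column_flagged_once(self, rng):
        a = rng.normal(size=30)
        tab = pd.DataFrame({"surf_do": a, "deep_do": a, "sed_cn": rng.normal(size=30)})
        retained, report = screen_collinearity(tab, threshold=0.95)
        assert "surf_do" in retained and "deep_do" not in retained
        flagged = report[report.flagged]
        assert len(flagged) == 1

    def test_orthogonal_columns_both_kept(self):
        tab = pd.DataFrame(
            {"surf_do": [1.0, -1.0, 1.0, -1.0], "deep_do": [1.0, 1.0, -1.0, -1.0],
             "sed_cn": [1.0, 2.0, 3.0, 4.0]}
        )
        retained, report = screen_collinearity(tab, threshold=0.9)
        assert {"surf_do", "deep_do"} <= set(retained)

    def test_r_matches_covariance_oracle(self, rng):
        import oracles

        tab = pd.DataFrame(rng.normal(size=(25, 3)), columns=["surf_do", "deep_do", "sed_cn"])
        _, report = screen_collinearity(tab, threshold=0.99)
        for _, row in report.iterrows():
            expect = oracles.pearson_r(tab[row.var_a], tab[row.var_b])
            assert row.r == pytest.approx(expect, abs=1e-12)

    def test_constant_column_flagged(self, rng):
        tab = pd.DataFrame(
            {"surf_do": np.ones(10), "deep_do": rng.normal(size=10),
             "sed_cn": rng.normal(size=10)}
        )
        retained, report = screen_collinearity(tab, threshold=0.8)
        assert "surf_do" not in retained
        assert report[(report.var_a == "surf_do") & (report.var_b == "surf_do")].flagged.all()
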