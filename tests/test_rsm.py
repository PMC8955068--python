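import numpy as np
import pytest

from nanoform import fixtures as fx
from nanoform import rsm
from nanoform.design import FactorDef, build_bbd
from nanoform.errors import (
    SingularFitError,
    TransformDomainError,
    UndefinedStatisticError,
)


class TestTransforms:
    @pytest.mark.parametrize("kind,value,expected", [
        ("sqrt", 230.8, 15.192103),
        ("inverse", 54.1, 0.01848429),
        ("identity", 42.0, 42.0),
    ])
    def test_forward_values(self, kind, value, expected):
        out = rsm.apply_transform([value], rsm.Transform(kind))
        assert out[0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("kind,values", [
        ("sqrt", [4.0, -1.0]),
        ("inverse", [2.0, 0.0]),
    ])
    def test_domain_violations_name_the_run(self, kind, values):
        with pytest.raises(TransformDomainError, match="index 1"):
            rsm.apply_transform(values, rsm.Transform(kind))

    @pytest.mark.parametrize("kind", ["identity", "sqrt", "inverse"])
    def test_invert_is_exact_functional_inverse(self, kind):
        tf = rsm.Transform(kind)
        y = np.array([0.5, 1.0, 25.0, 230.8])
        assert np.allclose(tf.invert(tf.apply(y)), y)


class TestTermSet:
    def test_intercept_always_present(self):
        assert "intercept" in rsm.TermSet(["x1"])

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="parent"):
            rsm.TermSet(["x1", "x1x3"])  # missing x3

    def test_full_quadratic_has_ten_terms(self):
        assert len(rsm.TermSet.full_quadratic()) == 10


class TestFit:
    def test_ps_linear_matches_published_equation(self, ps_model):
        c = ps_model.coefficients()
        assert c["intercept"] == pytest.approx(12.7979, abs=5e-5)
        assert c["x1"] == pytest.approx(1.87247, abs=5e-6)
        assert c["x2"] == pytest.approx(-0.580015, abs=5e-7)
        assert c["x3"] == pytest.approx(-0.140025, abs=5e-7)

    def test_cdr_linear_matches_published_equation(self, cdr_model):
        c = cdr_model.coefficients()
        assert c["intercept"] == pytest.approx(71.2471, abs=5e-5)
        assert c["x3"] == pytest.approx(13.0875, abs=5e-5)

    def test_closed_form_oracle_agrees_with_ols(self, design17):
        """On a BBD the linear coefficients have a closed form:
        intercept = mean(y), b_j = (sum y at xj=+1 - sum y at xj=-1)/8."""
        for resp, tf in [("PS", rsm.SQRT), ("CDR", rsm.IDENTITY),
                         ("ZP", rsm.IDENTITY)]:
            y = fx.response_values(resp)
            model = rsm.fit_rsm(design17, y, rsm.TermSet.linear(), tf)
            oracle = rsm.closed_form_linear_fit(design17, y, tf)
            for term, value in oracle.items():
                assert model.coefficients()[term] == pytest.approx(value, abs=1e-9)

    def test_noiseless_synthetic_recovered_to_machine_precision(self):
        factors = (FactorDef("a", 0, 1), FactorDef("b", 0, 1), FactorDef("c", 0, 1))
        design = build_bbd(factors, 3)
        truth = np.array([10.0, 2.0, -1.5, 0.25, 0.8, -0.3, 0.0, 1.1, -0.9, 0.4])
        X = rsm.model_matrix(rsm.TermSet.full_quadratic(), design.coded)
        y = X @ truth
        model = rsm.fit_rsm(design, y, rsm.TermSet.full_quadratic())
        assert np.allclose(model.coef, truth, atol=1e-10)
        assert np.allclose(model.residuals, 0.0, atol=1e-10)

    def test_rank_deficiency_detected(self):
        factors = (FactorDef("a", 0, 1), FactorDef("b", 0, 1), FactorDef("c", 0, 1))
        design = build_bbd(factors, 0)
        from nanoform.design import DesignMatrix
        # duplicate x1 into x2: coded columns become collinear
        coded = design.coded.copy()
        coded[:, 1] = coded[:, 0]
        bad = DesignMatrix(factors=factors, coded=coded)
        with pytest.raises(SingularFitError):
            rsm.fit_rsm(bad, np.arange(12.0), rsm.TermSet.linear())


class TestAnova:
    def test_ps_model_and_lack_of_fit_statistics(self, ps_model):
        table = rsm.anova_type3(ps_model)
        assert table.model_f == pytest.approx(416.50, rel=5e-4)
        assert table.lof_f == pytest.approx(0.3386, rel=2e-3)
        assert table.lof_p == pytest.approx(0.9183, rel=2e-3)
        assert (table.df_lof, table.df_pe) == (9, 4)

    def test_zeta_potential_has_no_significant_factor(self, design17):
        model = rsm.fit_rsm(design17, fx.response_values("ZP"),
                            rsm.TermSet.linear(), rsm.IDENTITY, "ZP")
        table = rsm.anova_type3(model)
        assert all(p > 0.05 for p in table.term_p.values())

    def test_sum_of_squares_decomposition(self, ps_model):
        """SST = SSR + SSE and SSE = SS_pure_error + SS_lack_of_fit."""
        y = ps_model.y_transformed
        sse = float(ps_model.residuals @ ps_model.residuals)
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(np.sum((ps_model.fitted - y.mean()) ** 2))
        assert sst == pytest.approx(ssr + sse, rel=1e-10)
        from nanoform.rsm import _pure_error
        ss_pe, df_pe = _pure_error(ps_model)
        table = rsm.anova_type3(ps_model)
        ss_lof = table.lof_f * (ss_pe / df_pe) * table.df_lof
        assert sse == pytest.approx(ss_pe + ss_lof, rel=1e-10)

    def test_noiseless_linear_response_fully_explained(self):
        factors = (FactorDef("a", 0, 1), FactorDef("b", 0, 1), FactorDef("c", 0, 1))
        design = build_bbd(factors, 5)
        y = 3.0 + 2.0 * design.coded[:, 0] - design.coded[:, 2]
        y_noisy = y + np.concatenate([np.zeros(12), 1e-9 * np.arange(5)])
        model = rsm.fit_rsm(design, y_noisy, rsm.TermSet.linear())
        table = rsm.anova_type3(model)
        assert table.model_p < 1e-12

    def test_no_replicates_reports_lack_of_fit_unavailable(self):
        factors = (FactorDef("a", 0, 1), FactorDef("b", 0, 1), FactorDef("c", 0, 1))
        design = build_bbd(factors, 1)  # single center: no replicate group
        rng = np.random.default_rng(1)
        model = rsm.fit_rsm(design, rng.normal(10, 1, 13), rsm.TermSet.linear())
        table = rsm.anova_type3(model)
        assert table.lof_f is None and table.df_pe is None


class TestFitStats:
    def test_ps_diagnostic_panel(self, ps_model):
        s = rsm.fit_stats(ps_model)
        assert s.r2 == pytest.approx(0.9897, abs=5e-5)
        assert s.sd == pytest.approx(0.1573, abs=5e-5)
        assert s.cv_percent == pytest.approx(1.23, abs=5e-3)
        assert s.adequate_precision == pytest.approx(64.3041, rel=5e-4)
        assert s.pred_r2 == pytest.approx(0.9845, abs=5e-5)
        assert s.adj_r2 == pytest.approx(0.9873, abs=5e-5)

    def test_cdr_r2(self, cdr_model):
        assert rsm.fit_stats(cdr_model).r2 == pytest.approx(0.9915, abs=5e-5)

    def test_r2_family_ordering(self, fitted_models):
        for model in fitted_models.values():
            s = rsm.fit_stats(model)
            assert s.pred_r2 <= s.adj_r2 <= s.r2 <= 1.0

    def test_perfect_fit_r2_one(self):
        factors = (FactorDef("a", 0, 1), FactorDef("b", 0, 1), FactorDef("c", 0, 1))
        design = build_bbd(factors, 0)
        y = 1.0 + design.coded @ np.array([1.0, 2.0, 3.0])
        model = rsm.fit_rsm(design, y, rsm.TermSet.linear())
        s = rsm.fit_stats(model)
        assert s.r2 == pytest.approx(1.0)
        assert s.adj_r2 == pytest.approx(1.0)

    def test_constant_response_rejected(self):
        factors = (FactorDef("a", 0, 1), FactorDef("b", 0, 1), FactorDef("c", 0, 1))
        design = build_bbd(factors, 0)
        model = rsm.fit_rsm(design, np.full(12, 7.0), rsm.TermSet.linear())
        with pytest.raises(UndefinedStatisticError):
            rsm.fit_stats(model)


class TestReduction:
    def test_ee_reduction_retains_published_terms(self, ee_model):
        assert list(ee_model.terms) == [
            "intercept", "x1", "x2", "x3", "x1x3", "x1^2", "x2^2", "x3^2"]

    def test_ee_x1_coefficient(self, ee_model):
        assert ee_model.coefficients()["x1"] == pytest.approx(-0.0024, abs=5e-5)

    def test_alpha_one_returns_model_unchanged(self, design17):
        full = rsm.fit_rsm(design17, fx.response_values("EE"),
                           rsm.TermSet.full_quadratic(), rsm.INVERSE)
        reduced = rsm.reduce_model(full, alpha=1.0)
        assert list(reduced.terms) == list(full.terms)

    def test_all_significant_model_unchanged(self, ps_model):
        reduced = rsm.reduce_model(ps_model, alpha=0.05)
        assert list(reduced.terms) == list(ps_model.terms)


class TestPredict:
    def test_center_prediction_is_back_transformed_intercept(self, fitted_models):
        for model in fitted_models.values():
            expected = model.transform.invert(model.coefficients()["intercept"])
            assert rsm.predict(model, (0, 0, 0)) == pytest.approx(float(expected))

    def test_predictions_at_published_optimum(self, fitted_models):
        point = (-0.706, 0.6, 1.0)
        assert rsm.predict(fitted_models["PS"], point) == pytest.approx(119.8, rel=0.01)
        assert rsm.predict(fitted_models["CDR"], point) == pytest.approx(88.2, rel=0.005)

    def test_predict_reproduces_stored_fitted_values(self, ps_model):
        for row, fit_t in zip(ps_model.design.coded, ps_model.fitted):
            y = rsm.predict(ps_model, row)
            assert y == pytest.approx(float(ps_model.transform.invert(fit_t)))

    def test_extrapolation_guard(self, ps_model):
        with pytest.raises(ValueError, match="extrapolate"):
            rsm.predict(ps_model, (2.0, 0.0, 0.0))
        assert rsm.predict(ps_model, (2.0, 0.0, 0.0), extrapolate=True) > 0
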