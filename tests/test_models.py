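"""Prediction models, dependent-R² comparison, residual diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import implantfit as iff
from implantfit.cohort import Cohort
from implantfit.models import (
    FitError,
    LinearSizePredictor,
    compare_r_squared,
    fit_simple_regression,
    pearson_correlation,
    predict_implant,
    residual_diagnostics,
    steiger_z,
)


class TestFitSimpleRegression:
    def test_exact_line(self):
        fit = fit_simple_regression([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.3, 2.1, 4.7, 5.2, 9.9])
        y = np.array([2.0, 1.1, 5.3, 4.8, 11.2])
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        fit = fit_simple_regression(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=4,
            max_size=25,
            unique_by=lambda t: t[0],
        )
    )
    def test_r_squared_is_squared_pearson(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        if np.ptp(y) == 0:
            return
        fit = fit_simple_regression(x, y)
        assert fit.r_squared == pytest.approx(fit.pearson_r**2, abs=1e-10)

    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=4,
            max_size=25,
            unique_by=lambda t: t[0],
        )
    )
    def test_residuals_sum_to_zero(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        fit = fit_simple_regression(x, y)
        scale = max(np.abs(y).max(), 1.0)
        assert abs(fit.residuals.sum()) < 1e-8 * len(x) * scale

    def test_degenerate_inputs(self):
        with pytest.raises(FitError):
            fit_simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(FitError):
            fit_simple_regression([1.0, 2.0], [1.0, 2.0])

    def test_recovers_generating_models(self, large_corrected):
        """The four fitted models reproduce the calibrated relations."""
        corrected, _ = large_corrected
        fit_v = fit_simple_regression(
            corrected.column("v_healthy_pre"), corrected.column("i_ideal")
        )
        assert fit_v.slope == pytest.approx(0.78, rel=0.02)
        assert fit_v.intercept == pytest.approx(25.0, abs=5.0)
        assert fit_v.r_squared == pytest.approx(0.90, rel=0.02)
        fit_in = fit_simple_regression(
            corrected.column("v_healthy_pre"), corrected.column("i_inserted")
        )
        assert fit_in.slope == pytest.approx(0.66, rel=0.02)
        assert fit_in.intercept == pytest.approx(71.0, abs=5.0)


class TestLinearSizePredictorApi:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = LinearSizePredictor(predictor_name="v", outcome_name="i")
        assert clone(est).get_params() == est.get_params()
        x = np.linspace(100, 500, 30)
        y = 0.7 * x + 30 + np.sin(x)
        est.fit(x.reshape(-1, 1), y)
        assert est.slope_ == pytest.approx(0.7, rel=0.01)
        assert est.score(x.reshape(-1, 1), y) == pytest.approx(est.r_squared_, abs=1e-6)
        pred = est.predict([[200.0]])
        assert pred[0] == pytest.approx(est.slope_ * 200 + est.intercept_)

    def test_predict_requires_fit(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            LinearSizePredictor().predict([[1.0]])

    def test_multicolumn_rejected(self):
        with pytest.raises(ValueError):
            LinearSizePredictor().fit(np.ones((5, 2)), np.ones(5))


class TestPearsonCorrelation:
    def test_perfect_line(self):
        r, p = pearson_correlation([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_cohort_correlations(self, large_cohort):
        cohort, _ = large_cohort
        r_v, p_v = pearson_correlation(
            cohort.column("i_inserted"), cohort.column("v_healthy_pre")
        )
        r_w, p_w = pearson_correlation(
            cohort.column("i_inserted"), cohort.column("w_mast")
        )
        assert r_v == pytest.approx(0.938, rel=0.01)
        assert r_w == pytest.approx(0.900, rel=0.01)
        assert p_v < 1e-10 and p_w < 1e-10


def _null_cohort(seed: int, n: int = 56) -> Cohort:
    """Both predictors carry identical information about the outcome."""
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, 1.0, n)
    y = 300 + 50 * (s + rng.normal(0.0, 0.5, n))
    xa = 300 + 50 * (s + rng.normal(0.0, 0.4, n))
    xb = 300 + 50 * (s + rng.normal(0.0, 0.4, n))
    return Cohort(
        pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "v_healthy_pre": xa,
                "v_affected_pre": xa,
                "w_mast": xb,
                "i_inserted": y,
                "v_recon_post": y,
                "v_healthy_post": y,
            }
        )
    )


class TestCompareRSquared:
    def test_identical_predictors(self, hand_cohort):
        r = compare_r_squared(
            hand_cohort, "i_inserted", "v_healthy_pre", "v_healthy_pre",
            n_boot=1000, seed=0,
        )
        assert r.delta_r2 == 0.0
        assert r.p_value == pytest.approx(1.0)
        rs = compare_r_squared(
            hand_cohort, "i_inserted", "v_healthy_pre", "v_healthy_pre",
            method="steiger",
        )
        assert rs.p_value == pytest.approx(1.0)

    def test_delta_identity(self, large_corrected):
        corrected, _ = large_corrected
        r = compare_r_squared(
            corrected, "i_ideal", "v_healthy_pre", "w_mast",
            method="steiger",
        )
        assert r.delta_r2 == r.r2_a - r.r2_b
        assert r.r2_a > r.r2_b

    def test_seed_determinism(self):
        cohort = _null_cohort(3)
        a = compare_r_squared(cohort, "i_inserted", "v_healthy_pre", "w_mast",
                              n_boot=1500, seed=7)
        b = compare_r_squared(cohort, "i_inserted", "v_healthy_pre", "w_mast",
                              n_boot=1500, seed=7)
        assert a.p_value == b.p_value

    def test_usage_errors(self, hand_cohort):
        with pytest.raises(ValueError, match="unknown method"):
            compare_r_squared(hand_cohort, "i_inserted", "v_healthy_pre",
                              "w_mast", method="anova")
        with pytest.raises(ValueError, match="n_boot"):
            compare_r_squared(hand_cohort, "i_inserted", "v_healthy_pre",
                              "w_mast", n_boot=10)

    def test_large_sample_significance(self):
        """At n = 10^4 the volume predictor is decisively better under both
        methods."""
        cohort, _ = iff.generate_cohort(iff.default_calibration(n=10_000, seed=42))
        corrected, _ = iff.compute_ideal_cohort(cohort)
        pb = compare_r_squared(corrected, "i_ideal", "v_healthy_pre", "w_mast",
                               method="paired_bootstrap", n_boot=2000, seed=1)
        assert pb.p_value < 0.001
        sg = compare_r_squared(corrected, "i_ideal", "v_healthy_pre", "w_mast",
                               method="steiger")
        assert sg.p_value < 0.001

    def test_beta_propagation_changes_replicates(self):
        """Re-estimating beta inside replicates is a different procedure from
        holding the corrected outcome fixed; both must run."""
        cohort, _ = iff.generate_cohort(iff.default_calibration(n=56, seed=13))
        corrected, _ = iff.compute_ideal_cohort(cohort)
        a = compare_r_squared(corrected, "i_ideal", "v_healthy_pre", "w_mast",
                              n_boot=1000, seed=5, propagate_beta=True)
        b = compare_r_squared(corrected, "i_ideal", "v_healthy_pre", "w_mast",
                              n_boot=1000, seed=5, propagate_beta=False)
        assert a.r2_a == b.r2_a  # point estimates identical
        assert a.method == b.method == "paired_bootstrap"


class TestSteigerZ:
    def test_sign_and_symmetry(self):
        z_ab, p = steiger_z(0.9, 0.7, 0.6, 56)
        z_ba, p2 = steiger_z(0.7, 0.9, 0.6, 56)
        assert z_ab > 0 and z_ba == pytest.approx(-z_ab)
        assert p == pytest.approx(p2)

    def test_equal_correlations_give_p_one(self):
        z, p = steiger_z(0.8, 0.8, 0.5, 56)
        assert z == 0.0 and p == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(0.9, 0.7, 0.6, 3)


class TestResidualDiagnostics:
    def _fit(self, x, y):
        return fit_simple_regression(x, y)

    def test_well_specified_model_passes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(300, 150, 56)
        y = 0.78 * x + 25 + rng.normal(0, 39, 56)
        rep = residual_diagnostics(self._fit(x, y), x)
        assert rep.applicable
        assert rep.passed in (True, False)
        assert 0 <= rep.normality_p <= 1

    def test_type_i_rates_near_nominal(self):
        """Each test rejects a correct model at roughly its nominal 5%."""
        rng = np.random.default_rng(99)
        rejects = np.zeros(3)
        k = 200
        for _ in range(k):
            x = rng.normal(300, 150, 56)
            y = 0.78 * x + 25 + rng.normal(0, 39, 56)
            rep = residual_diagnostics(self._fit(x, y), x)
            rejects += [
                rep.normality_p < 0.05,
                rep.heteroscedasticity_p < 0.05,
                rep.linearity_p < 0.05,
            ]
        for rate in rejects / k:
            assert 0.01 <= rate <= 0.10

    def test_heteroscedasticity_power(self):
        """Variance growing with x² is caught at n = 200."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(40):
            x = rng.uniform(100, 600, 200)
            y = 0.78 * x + 25 + rng.normal(0, 1, 200) * (x / 8)
            rep = residual_diagnostics(self._fit(x, y), x)
            hits += rep.heteroscedasticity_p < 0.05
        assert hits / 40 > 0.8

    def test_nonlinearity_detected(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(100, 600, 200)
        y = 0.002 * (x - 350) ** 2 + 0.5 * x + rng.normal(0, 5, 200)
        rep = residual_diagnostics(self._fit(x, y), x)
        assert rep.linearity_p < 0.01
        assert rep.passed is False

    def test_exact_fit_not_applicable(self):
        x = np.linspace(1, 10, 12)
        rep = residual_diagnostics(self._fit(x, 2 * x + 1), x)
        assert not rep.applicable
        assert rep.passed is None
        assert math.isnan(rep.normality_stat)

    def test_too_few_residuals(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            residual_diagnostics(self._fit(x, [1.0, 2.1, 2.9, 4.2]), x)


class TestPredictImplant:
    def test_reference_volume_formula(self):
        assert predict_implant(276.0, "volume") == pytest.approx(240.28)
        assert predict_implant(276.0, (0.78, 25.0)) == pytest.approx(240.28)

    def test_reference_weight_formula(self):
        assert predict_implant(252.0, "weight") == pytest.approx(248.68)

    def test_zero_input_returns_intercept(self):
        assert predict_implant(0.0, (0.78, 25.0)) == 25.0

    def test_regression_fit_and_estimator_inputs(self):
        fit = fit_simple_regression([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert predict_implant(5.0, fit) == pytest.approx(10.0)
        est = LinearSizePredictor().fit([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert predict_implant(5.0, est) == pytest.approx(10.0)

    def test_unknown_formula_key(self):
        with pytest.raises(ValueError, match="unknown formula"):
            predict_implant(100.0, "density")

    def test_non_finite_coefficients(self):
        with pytest.raises(ValueError):
            predict_implant(100.0, (float("nan"), 0.0))
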