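"""Simple-linear prediction models, dependent-R² comparison, and residual
diagnostics.

The implant prediction formulas are simple ordinary least squares fits of
implant volume (inserted or ideal, cc) on one morphological predictor — the
preoperative healthy-breast 3D volume (cc) or the mastectomy specimen weight
(g). Prediction performance is the coefficient of determination R², and two
predictors fitted on the *same* patients are compared with either a paired
patient-level bootstrap (default) or Steiger's z-test for dependent
overlapping correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort

#: Published coefficients (slope, intercept in cc) of the clinical series the
#: default calibration reproduces, keyed by predictor.
REFERENCE_FORMULAS = {
    "volume": (0.78, 25.0),  # ideal implant (cc) from healthy-breast 3D volume (cc)
    "weight": (0.84, 37.0),  # ideal implant (cc) from mastectomy specimen weight (g)
}


class FitError(ValueError):
    """Regression cannot be fit (too few points or degenerate predictor)."""


@dataclass
class RegressionFit:
    """A fitted simple linear regression ``y = slope * x + intercept``.

    ``p_value`` is the two-sided t-test of the slope; ``residual_sd`` is the
    root mean squared residual with 2 degrees of freedom lost.
    """

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    residual_sd: float
    n: int
    residuals: np.ndarray = field(repr=False)
    predictor_name: str = "x"
    outcome_name: str = "y"

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        """JSON-ready summary; per-patient residuals are deliberately
        summarized by ``residual_sd`` rather than serialized."""
        return {
            "predictor": self.predictor_name,
            "outcome": self.outcome_name,
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "residual_sd": self.residual_sd,
            "n": self.n,
        }


class LinearSizePredictor(RegressorMixin, BaseEstimator):
    """Scikit-learn style simple linear regression for implant sizing.

    A thin estimator around the closed-form OLS fit of one outcome on one
    predictor, exposing the clinically reported quantities (slope, intercept,
    Pearson r, R², slope p-value) as fitted attributes.

    Parameters
    ----------
    predictor_name, outcome_name : str
        Labels carried into reports.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted coefficients (implant cc per predictor unit; cc).
    pearson_r_, r_squared_, p_value_ : float
        Correlation, coefficient of determination and two-sided slope test.
    residuals_ : ndarray of shape (n,)
        Per-patient residuals, in fit order.
    residual_sd_ : float
        Residual SD with ``ddof=2``.
    """

    def __init__(self, predictor_name: str = "x", outcome_name: str = "y"):
        self.predictor_name = predictor_name
        self.outcome_name = outcome_name

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError(
                    f"exactly one predictor expected, got {x.shape[1]} columns"
                )
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be one-dimensional and equal-length")
        if x.size < 3:
            raise FitError(f"at least 3 points required, got {x.size}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise FitError("non-finite values in regression inputs")
        if np.ptp(x) == 0:
            raise FitError("predictor has zero variance")

        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.pearson_r_ = float(res.rvalue)
        self.r_squared_ = float(res.rvalue**2)
        self.p_value_ = float(res.pvalue)
        self.stderr_ = float(res.stderr)
        self.residuals_ = y - (self.slope_ * x + self.intercept_)
        self.residual_sd_ = (
            float(np.sqrt(np.sum(self.residuals_**2) / (x.size - 2)))
            if x.size > 2
            else 0.0
        )
        self.n_ = int(x.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.slope_ * x + self.intercept_

    def to_fit(self) -> RegressionFit:
        check_is_fitted(self, "slope_")
        return RegressionFit(
            slope=self.slope_,
            intercept=self.intercept_,
            pearson_r=self.pearson_r_,
            r_squared=self.r_squared_,
            p_value=self.p_value_,
            residual_sd=self.residual_sd_,
            n=self.n_,
            residuals=self.residuals_,
            predictor_name=self.predictor_name,
            outcome_name=self.outcome_name,
        )


def fit_simple_regression(
    x, y, predictor_name: str = "x", outcome_name: str = "y"
) -> RegressionFit:
    """Closed-form OLS of ``y`` on ``x`` with intercept."""
    est = LinearSizePredictor(predictor_name=predictor_name, outcome_name=outcome_name)
    return est.fit(x, y).to_fit()


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 points required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# dependent-R² comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """Comparison of the R² of two predictors of the same outcome."""

    r2_a: float
    r2_b: float
    p_value: float
    method: str
    n: int
    predictor_a: str = "a"
    predictor_b: str = "b"
    n_boot: int = 0
    seed: Optional[int] = None

    @property
    def delta_r2(self) -> float:
        return self.r2_a - self.r2_b

    def to_dict(self) -> dict:
        return {
            "predictor_a": self.predictor_a,
            "predictor_b": self.predictor_b,
            "r2_a": self.r2_a,
            "r2_b": self.r2_b,
            "delta_r2": self.delta_r2,
            "p_value": self.p_value,
            "method": self.method,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _bootstrap_r2(
    y: np.ndarray,
    xa: np.ndarray,
    xb: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    beta_inputs: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = None,
    chunk: int = 1000,
) -> np.ndarray:
    """Bootstrap replicates of ΔR², resampling patients with replacement.

    When ``beta_inputs = (v_pre, i_inserted, v_recon_post, v_healthy_post)``
    is given, the corrected outcome is rebuilt inside each replicate: the
    stage-1 slope is re-estimated on the resampled patients, so its sampling
    uncertainty propagates into the comparison.
    """
    n = y.size
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        xa_s, xb_s = xa[idx], xb[idx]
        if beta_inputs is None:
            y_s = y[idx]
        else:
            v_pre, i_ins, v_rec, v_heal = (arr[idx] for arr in beta_inputs)
            cov = (v_pre * i_ins).mean(axis=1) - v_pre.mean(axis=1) * i_ins.mean(axis=1)
            var = v_pre.var(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = cov / var
            y_s = i_ins - beta[:, None] * (v_rec - v_heal)

        def r2(x_s: np.ndarray) -> np.ndarray:
            cxy = (x_s * y_s).mean(axis=1) - x_s.mean(axis=1) * y_s.mean(axis=1)
            vx = x_s.var(axis=1)
            vy = y_s.var(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return cxy**2 / (vx * vy)

        out[done : done + b] = r2(xa_s) - r2(xb_s)
        done += b
    return out


def steiger_z(
    r_ya: float, r_yb: float, r_ab: float, n: int
) -> Tuple[float, float]:
    """Steiger's z-test for two dependent, overlapping correlations.

    Tests ``|corr(y, a)| = |corr(y, b)|`` observed on the same n subjects,
    using Fisher-transformed correlations and the pooled-correlation estimate
    of their covariance. Returns (z, two-sided p).
    """
    if n <= 3:
        raise ValueError("Steiger's test requires n > 3")
    rbar = 0.5 * (r_ya + r_yb)
    num = r_ab * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
        1.0 - 2.0 * rbar**2 - r_ab**2
    )
    cov = num / (1.0 - rbar**2) ** 2
    za, zb = np.arctanh(r_ya), np.arctanh(r_yb)
    if za == zb:
        return 0.0, 1.0
    denom = 2.0 - 2.0 * cov
    if denom <= 0:  # perfectly dependent predictors: any difference is exact
        return math.copysign(math.inf, za - zb), 0.0
    z = (za - zb) * math.sqrt((n - 3) / denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_r_squared(
    cohort: Union[Cohort, "np.ndarray"],
    outcome: str,
    predictor_a: str,
    predictor_b: str,
    method: str = "paired_bootstrap",
    n_boot: int = 5000,
    seed: int = 0,
    propagate_beta: bool = True,
) -> ComparisonResult:
    """Compare the R² of two predictors of one outcome on the same cohort.

    ``paired_bootstrap`` resamples patients with replacement, refits both
    simple regressions per replicate and reports the two-sided percentile
    p-value of ΔR² against 0. When the outcome is the corrected ideal volume
    (``i_ideal``) and ``propagate_beta`` is true, the stage-1 slope and the
    corrected outcome are re-computed within each replicate. ``steiger``
    applies the dependent-overlapping-correlation z-test, which treats the
    outcome as fixed data.
    """
    y = cohort.column(outcome)
    xa = cohort.column(predictor_a)
    xb = cohort.column(predictor_b)
    n = y.size
    if n < 4:
        raise FitError("comparison requires at least 4 patients")
    r2_a = pearson_correlation(xa, y)[0] ** 2
    r2_b = pearson_correlation(xb, y)[0] ** 2

    if method == "paired_bootstrap":
        if n_boot < 1000:
            raise ValueError("n_boot must be at least 1000")
        beta_inputs = None
        if propagate_beta and outcome == "i_ideal":
            beta_inputs = (
                cohort.column("v_healthy_pre"),
                cohort.column("i_inserted"),
                cohort.column("v_recon_post"),
                cohort.column("v_healthy_post"),
            )
        rng = np.random.default_rng(seed)
        delta = _bootstrap_r2(y, xa, xb, n_boot, rng, beta_inputs=beta_inputs)
        delta = delta[np.isfinite(delta)]
        if delta.size == 0:
            raise FitError("all bootstrap replicates degenerate")
        lo = np.mean(delta <= 0.0)
        hi = np.mean(delta >= 0.0)
        p = min(1.0, 2.0 * min(lo, hi))
    elif method == "steiger":
        r_ya = math.copysign(math.sqrt(r2_a), 1.0)
        r_yb = math.copysign(math.sqrt(r2_b), 1.0)
        r_ab = abs(pearson_correlation(xa, xb)[0])
        _, p = steiger_z(r_ya, r_yb, r_ab, n)
        n_boot = 0
    else:
        raise ValueError(f"unknown method {method!r}")

    return ComparisonResult(
        r2_a=r2_a,
        r2_b=r2_b,
        p_value=float(p),
        method=method,
        n=n,
        predictor_a=predictor_a,
        predictor_b=predictor_b,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual-analysis battery for one simple regression at α = 0.05.

    Normality: Shapiro–Wilk on residuals. Homoscedasticity: Breusch–Pagan
    against the predictor. Linearity: t-test of a quadratic term added to the
    mean model (RESET-style). ``applicable`` is False for degenerate
    (zero-residual) fits, in which case all statistics are NaN.
    """

    normality_stat: float
    normality_p: float
    heteroscedasticity_stat: float
    heteroscedasticity_p: float
    linearity_stat: float
    linearity_p: float
    alpha: float = 0.05
    applicable: bool = True

    @property
    def passed(self) -> Optional[bool]:
        if not self.applicable:
            return None
        return bool(
            self.normality_p > self.alpha
            and self.heteroscedasticity_p > self.alpha
            and self.linearity_p > self.alpha
        )

    def to_dict(self) -> dict:
        def _f(v: float):
            return None if not math.isfinite(v) else v

        return {
            "normality": {"stat": _f(self.normality_stat), "p": _f(self.normality_p)},
            "heteroscedasticity": {
                "stat": _f(self.heteroscedasticity_stat),
                "p": _f(self.heteroscedasticity_p),
            },
            "linearity": {"stat": _f(self.linearity_stat), "p": _f(self.linearity_p)},
            "alpha": self.alpha,
            "applicable": self.applicable,
            "passed": self.passed,
        }


def residual_diagnostics(fit: RegressionFit, x) -> DiagnosticsReport:
    """Run the residual-analysis battery for a fitted simple regression."""
    resid = np.asarray(fit.residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    if resid.size < 8:
        raise ValueError("residual diagnostics require at least 8 residuals")
    if resid.size != x.size:
        raise ValueError("x must match the residual vector length")
    scale = max(np.max(np.abs(resid)), 1.0)
    if np.allclose(resid, 0.0, atol=1e-12 * scale) or np.std(resid) == 0.0:
        nan = float("nan")
        return DiagnosticsReport(nan, nan, nan, nan, nan, nan, applicable=False)

    sw_stat, sw_p = stats.shapiro(resid)

    exog = sm.add_constant(x)
    bp_stat, bp_p, _, _ = sm.stats.diagnostic.het_breuschpagan(resid, exog)

    # quadratic-term t-test: residuals are already orthogonal to (1, x), so
    # regressing them on (1, x, x²) isolates the curvature term
    xc = x - x.mean()  # centring limits collinearity between x and x²
    aug = sm.add_constant(np.column_stack([xc, xc**2]))
    ols = sm.OLS(resid, aug).fit()
    t_stat = float(ols.tvalues[2])
    t_p = float(ols.pvalues[2])

    return DiagnosticsReport(
        normality_stat=float(sw_stat),
        normality_p=float(sw_p),
        heteroscedasticity_stat=float(bp_stat),
        heteroscedasticity_p=float(bp_p),
        linearity_stat=t_stat,
        linearity_p=t_p,
    )


def predict_implant(value: float, fit_or_coeffs) -> float:
    """Predicted implant volume (cc) from one predictor value.

    ``fit_or_coeffs`` may be a :class:`RegressionFit`, a fitted
    :class:`LinearSizePredictor`, a ``(slope, intercept)`` pair, or one of
    the :data:`REFERENCE_FORMULAS` keys (``"volume"`` / ``"weight"``).
    """
    if isinstance(fit_or_coeffs, str):
        try:
            slope, intercept = REFERENCE_FORMULAS[fit_or_coeffs]
        except KeyError:
            raise ValueError(
                f"unknown formula {fit_or_coeffs!r}; "
                f"expected one of {sorted(REFERENCE_FORMULAS)}"
            )
    elif isinstance(fit_or_coeffs, RegressionFit):
        slope, intercept = fit_or_coeffs.slope, fit_or_coeffs.intercept
    elif isinstance(fit_or_coeffs, LinearSizePredictor):
        check_is_fitted(fit_or_coeffs, "slope_")
        slope, intercept = fit_or_coeffs.slope_, fit_or_coeffs.intercept_
    else:
        slope, intercept = fit_or_coeffs
    if not (math.isfinite(slope) and math.isfinite(intercept)):
        raise ValueError("coefficients must be finite")
    return float(slope * value + intercept)
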