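"""Two-stage construction of the ideal implant volume.

The implant actually inserted at surgery is rarely the size that would have
produced symmetric breasts, but the residual asymmetry visible in the
three-month postoperative 3D scans tells us by how much it missed. The ideal
implant volume is the inserted volume corrected by that asymmetry:

    i_ideal = i_inserted - beta * (v_recon_post - v_healthy_post)

where ``beta`` converts a breast-volume difference into an equivalent
implant-volume difference. Stage 1 estimates ``beta`` as the OLS slope of
inserted implant volume on preoperative breast volume across the cohort (a
beta of 0.7 means a 100 cc larger breast takes a 70 cc larger implant);
stage 2 applies the correction record-wise. The naive variant fixes
``beta = 1``, i.e. adds or subtracts the raw postoperative volume difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .models import FitError, LinearSizePredictor, RegressionFit, fit_simple_regression


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of one correction pass over a cohort."""

    beta_hat: float
    beta_fit: Optional[RegressionFit]
    ideal_volumes: np.ndarray
    method: str  # "beta_corrected" | "naive"

    def __post_init__(self):
        if self.method == "naive" and self.beta_hat != 1.0:
            raise ValueError("naive correction requires beta_hat = 1")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta_hat": self.beta_hat,
            "mean_ideal": float(np.mean(self.ideal_volumes))
            if self.ideal_volumes.size
            else None,
            "sd_ideal": float(np.std(self.ideal_volumes, ddof=1))
            if self.ideal_volumes.size > 1
            else None,
            "n": int(self.ideal_volumes.size),
            "beta_fit": self.beta_fit.to_dict() if self.beta_fit is not None else None,
        }


def estimate_beta(cohort: Cohort, predictor_side: str = "healthy") -> RegressionFit:
    """Stage-1 OLS of inserted implant volume on preoperative breast volume.

    ``predictor_side`` chooses the healthy (contralateral, default) or the
    affected breast as the preoperative volume; the slope is the beta used by
    the correction.
    """
    if len(cohort) < 3:
        raise FitError("beta estimation requires at least 3 patients")
    col = {"healthy": "v_healthy_pre", "affected": "v_affected_pre"}.get(predictor_side)
    if col is None:
        raise ValueError("predictor_side must be 'healthy' or 'affected'")
    return fit_simple_regression(
        cohort.column(col),
        cohort.column("i_inserted"),
        predictor_name=col,
        outcome_name="i_inserted",
    )


def correct_implant_volume(i_inserted, beta, v_recon_post, v_healthy_post):
    """Apply the asymmetry correction to one or more implant volumes.

    Returns ``i_inserted - beta * (v_recon_post - v_healthy_post)``; larger
    than the inserted volume when the reconstructed side came out smaller.
    Scalar in, scalar out; arrays broadcast.
    """
    arrs = [np.asarray(a, dtype=float) for a in (i_inserted, beta, v_recon_post, v_healthy_post)]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("correction inputs must be finite")
    i, b, vr, vh = arrs
    out = i - b * (vr - vh)
    return float(out) if out.ndim == 0 else out


def naive_correction(i_inserted, v_recon_post, v_healthy_post):
    """Correction with beta fixed to 1: raw add/subtract of the postoperative
    volume difference."""
    return correct_implant_volume(i_inserted, 1.0, v_recon_post, v_healthy_post)


class BetaCorrector(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer filling a cohort's ideal implant volume.

    ``fit`` estimates the stage-1 slope on the cohort (in-sample, matching
    the clinical procedure), ``transform`` applies the correction to every
    record and returns a cohort whose ``i_ideal`` column is populated.

    Parameters
    ----------
    method : {"beta_corrected", "naive"}
        Naive fixes beta = 1 and skips the stage-1 regression.
    predictor_side : {"healthy", "affected"}
        Which preoperative volume drives the stage-1 regression.
    beta_override : float, optional
        Bypass estimation entirely (e.g. a literature beta, or the known
        generating slope in simulation studies).
    round_beta : int, optional
        Decimal places to round the estimated beta to before correcting —
        sensitivity option mirroring a two-decimal published slope; default
        uses full precision.

    Attributes
    ----------
    beta_ : float
        The slope applied by :meth:`transform`.
    beta_fit_ : RegressionFit or None
        Stage-1 regression (None for naive or overridden beta).
    """

    def __init__(
        self,
        method: str = "beta_corrected",
        predictor_side: str = "healthy",
        beta_override: Optional[float] = None,
        round_beta: Optional[int] = None,
    ):
        self.method = method
        self.predictor_side = predictor_side
        self.beta_override = beta_override
        self.round_beta = round_beta

    def fit(self, cohort: Cohort, y=None):
        if self.method not in ("beta_corrected", "naive"):
            raise ValueError("method must be 'beta_corrected' or 'naive'")
        if self.method == "naive":
            self.beta_ = 1.0
            self.beta_fit_ = None
        elif self.beta_override is not None:
            self.beta_ = float(self.beta_override)
            self.beta_fit_ = None
        else:
            fit = estimate_beta(cohort, predictor_side=self.predictor_side)
            beta = fit.slope
            if self.round_beta is not None:
                beta = round(beta, self.round_beta)
            self.beta_ = float(beta)
            self.beta_fit_ = fit
        return self

    def transform(self, cohort: Cohort) -> Cohort:
        check_is_fitted(self, "beta_")
        ideal = correct_implant_volume(
            cohort.column("i_inserted"),
            self.beta_,
            cohort.column("v_recon_post"),
            cohort.column("v_healthy_post"),
        )
        ideal = np.atleast_1d(ideal)
        if np.any(ideal <= 0):
            warnings.warn(
                f"{int(np.sum(ideal <= 0))} corrected ideal volume(s) are "
                "non-positive; retained unclipped",
                stacklevel=2,
            )
        return cohort.with_ideal(ideal)

    def result(self, cohort: Cohort) -> CorrectionResult:
        """Transform and package beta with the corrected volumes."""
        corrected = self.transform(cohort)
        return CorrectionResult(
            beta_hat=self.beta_,
            beta_fit=self.beta_fit_,
            ideal_volumes=corrected.column("i_ideal"),
            method=self.method,
        )


def compute_ideal_cohort(
    cohort: Cohort,
    method: str = "beta_corrected",
    predictor_side: str = "healthy",
    beta_override: Optional[float] = None,
    round_beta: Optional[int] = None,
) -> Tuple[Cohort, CorrectionResult]:
    """Estimate beta once on the whole cohort and fill every ``i_ideal``."""
    corrector = BetaCorrector(
        method=method,
        predictor_side=predictor_side,
        beta_override=beta_override,
        round_beta=round_beta,
    ).fit(cohort)
    corrected = corrector.transform(cohort)
    result = CorrectionResult(
        beta_hat=corrector.beta_,
        beta_fit=corrector.beta_fit_,
        ideal_volumes=corrected.column("i_ideal"),
        method=method,
    )
    return corrected, result
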