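"""End-to-end study pipeline: simulate (or load) → correct → fit → compare →
diagnose, emitting one reproducible report.

A single seed drives both the cohort generator and the bootstrap comparison
through independent child streams, so one integer reproduces every number in
the report.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, Optional, Tuple, Union

import numpy as np

from . import __version__
from .cohort import Cohort
from .correction import CorrectionResult, compute_ideal_cohort
from .models import (
    ComparisonResult,
    DiagnosticsReport,
    RegressionFit,
    compare_r_squared,
    fit_simple_regression,
    residual_diagnostics,
)
from .simulate import GeneratorConfig, generate_cohort
from .volumetry import AsymmetrySummary, asymmetry_summary

#: The four prediction models: outcome × predictor.
MODEL_SPECS = {
    "inserted_on_weight": ("i_inserted", "w_mast"),
    "inserted_on_volume": ("i_inserted", "v_healthy_pre"),
    "ideal_on_weight": ("i_ideal", "w_mast"),
    "ideal_on_volume": ("i_ideal", "v_healthy_pre"),
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class StudyReport:
    """Everything one analysis run produces.

    Fields mirror the study structure: cohort asymmetry summaries, the
    stage-1 beta regression, the correction pass, the four prediction-model
    fits, the dependent-R² comparison of the two ideal-volume predictors,
    and residual diagnostics per model.
    """

    asymmetry: Dict[str, AsymmetrySummary]
    stage1_fit: RegressionFit
    correction: CorrectionResult
    model_fits: Dict[str, RegressionFit]
    comparison: ComparisonResult
    diagnostics: Dict[str, DiagnosticsReport]
    config_echo: Union[GeneratorConfig, str]
    seed: Optional[int]
    n: int
    versions: Dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_dict(self) -> dict:
        cfg = self.config_echo
        return {
            "n": self.n,
            "seed": self.seed,
            "asymmetry": {k: v.to_dict() for k, v in self.asymmetry.items()},
            "stage1_fit": self.stage1_fit.to_dict(),
            "correction": self.correction.to_dict(),
            "model_fits": {k: v.to_dict() for k, v in self.model_fits.items()},
            "comparison": self.comparison.to_dict(),
            "diagnostics": {k: v.to_dict() for k, v in self.diagnostics.items()},
            "config_echo": cfg.model_dump() if isinstance(cfg, GeneratorConfig) else cfg,
            "versions": self.versions,
            "timestamp": self.timestamp,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _versions() -> Dict[str, str]:
    import pandas
    import scipy

    return {
        "implantfit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "python": platform.python_version(),
    }


def run_pipeline(
    config_or_cohort: Union[GeneratorConfig, Cohort],
    correction_method: str = "beta_corrected",
    comparison_method: str = "paired_bootstrap",
    n_boot: int = 5000,
    seed: Optional[int] = None,
    asymmetry_threshold: float = 20.0,
) -> Tuple[StudyReport, Cohort]:
    """Run the full analysis and return (report, corrected cohort).

    ``seed`` defaults to the generator config's seed (simulated input) or 0
    (file input); generator and bootstrap consume independent child streams
    of it.
    """
    if isinstance(config_or_cohort, GeneratorConfig):
        config = config_or_cohort
        if seed is None:
            seed = config.seed
        gen_seed, boot_seed = _child_seeds(seed)
        try:
            cohort, _ = generate_cohort(config.model_copy(update={"seed": gen_seed}))
        except Exception as exc:
            raise PipelineError("simulate", exc)
        config_echo: Union[GeneratorConfig, str] = config
    else:
        cohort = config_or_cohort
        if seed is None:
            seed = 0
        _, boot_seed = _child_seeds(seed)
        config_echo = cohort.provenance

    try:
        asym = {
            "preop": asymmetry_summary(cohort, "preop", threshold=asymmetry_threshold),
            "postop": asymmetry_summary(cohort, "postop", threshold=asymmetry_threshold),
        }
    except Exception as exc:
        raise PipelineError("asymmetry", exc)

    try:
        corrected, correction = compute_ideal_cohort(cohort, method=correction_method)
        stage1 = correction.beta_fit
        if stage1 is None:  # naive method: still report the stage-1 regression
            from .correction import estimate_beta

            stage1 = estimate_beta(cohort)
    except Exception as exc:
        raise PipelineError("correction", exc)

    try:
        fits = {
            name: fit_simple_regression(
                corrected.column(xcol),
                corrected.column(ycol),
                predictor_name=xcol,
                outcome_name=ycol,
            )
            for name, (ycol, xcol) in MODEL_SPECS.items()
        }
    except Exception as exc:
        raise PipelineError("model_fits", exc)

    try:
        comparison = compare_r_squared(
            corrected,
            outcome="i_ideal",
            predictor_a="v_healthy_pre",
            predictor_b="w_mast",
            method=comparison_method,
            n_boot=n_boot,
            seed=boot_seed,
        )
    except Exception as exc:
        raise PipelineError("comparison", exc)

    try:
        diagnostics = {
            name: residual_diagnostics(fit, corrected.column(MODEL_SPECS[name][1]))
            for name, fit in fits.items()
        }
    except Exception as exc:
        raise PipelineError("diagnostics", exc)

    report = StudyReport(
        asymmetry=asym,
        stage1_fit=stage1,
        correction=correction,
        model_fits=fits,
        comparison=comparison,
        diagnostics=diagnostics,
        config_echo=config_echo,
        seed=seed,
        n=len(cohort),
        versions=_versions(),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    return report, corrected


def _child_seeds(seed: int) -> Tuple[int, int]:
    """Two independent sub-seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    a, b = ss.spawn(2)
    return (
        int(a.generate_state(1, dtype=np.uint32)[0] % (2**31)),
        int(b.generate_state(1, dtype=np.uint32)[0] % (2**31)),
    )


def render_tables(report: StudyReport) -> str:
    """Human-readable summary of a study report."""
    lines = []
    lines.append(f"Cohort: n = {report.n} (seed {report.seed})")
    lines.append("")
    lines.append("Asymmetry (absolute % difference, healthy side as reference)")
    for key, a in report.asymmetry.items():
        lines.append(
            f"  {key:<7} mean {a.mean_abs_pct:6.1f} ± {a.sd_abs_pct:5.1f} %   "
            f"IQR {a.iqr_abs_pct[0]:.1f}–{a.iqr_abs_pct[1]:.1f} %   "
            f"> {a.threshold:.0f}%: {100 * a.prop_over_threshold:.1f}% of patients"
        )
    lines.append("")
    c = report.correction
    lines.append(
        f"Correction ({c.method}): beta = {c.beta_hat:.4f}; "
        f"mean ideal implant volume = "
        + (
            f"{np.mean(c.ideal_volumes):.1f} ± {np.std(c.ideal_volumes, ddof=1):.1f} cc"
            if c.ideal_volumes.size > 1
            else "n/a"
        )
    )
    lines.append("")
    lines.append("Prediction models (outcome = slope × predictor + intercept)")
    for name, f in report.model_fits.items():
        diag = report.diagnostics.get(name)
        if diag is None or diag.passed is None:
            verdict = "n/a"
        else:
            verdict = "ok" if diag.passed else "violated"
        lines.append(
            f"  {name:<20} {f.outcome_name} = {f.slope:.3f} × {f.predictor_name} "
            f"+ {f.intercept:.1f} cc   R² = {100 * f.r_squared:.1f}%  "
            f"p = {f.p_value:.3g}  residuals: {verdict}"
        )
    lines.append("")
    cmp_ = report.comparison
    lines.append(
        f"R² comparison ({cmp_.predictor_a} vs {cmp_.predictor_b}): "
        f"{cmp_.r2_a:.3f} vs {cmp_.r2_b:.3f} "
        f"(ΔR² = {cmp_.delta_r2:+.3f}, {cmp_.method}, p = {cmp_.p_value:.4g})"
    )
    return "\n".join(lines)
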