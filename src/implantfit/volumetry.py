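"""Breast-volume asymmetry statistics from paired 3D volumes.

The percentage volume difference uses the healthy (contralateral) side as
the reference denominator: ``(1 - v_other / v_healthy) * 100``, positive when
the other side is smaller than the healthy side. This convention applies
both preoperatively (healthy vs affected) and postoperatively (healthy vs
reconstructed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .cohort import Cohort


@dataclass(frozen=True)
class AsymmetrySummary:
    """Cohort-level summary of absolute volume asymmetry.

    ``prop_over_threshold`` is the fraction of patients whose absolute
    percentage difference strictly exceeds ``threshold`` (in %); IQRs are
    25th/75th percentiles with linear interpolation.
    """

    mean_abs_pct: float
    sd_abs_pct: float
    iqr_abs_pct: Tuple[float, float]
    mean_diff_cc: float
    sd_diff_cc: float
    iqr_diff_cc: Tuple[float, float]
    prop_over_threshold: float
    threshold: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.prop_over_threshold <= 1.0:
            raise ValueError("prop_over_threshold must lie in [0, 1]")
        if self.iqr_abs_pct[0] > self.iqr_abs_pct[1] or self.iqr_diff_cc[0] > self.iqr_diff_cc[1]:
            raise ValueError("IQR lower bound exceeds upper bound")

    def to_dict(self) -> dict:
        return {
            "mean_abs_pct": self.mean_abs_pct,
            "sd_abs_pct": self.sd_abs_pct,
            "iqr_abs_pct": list(self.iqr_abs_pct),
            "mean_diff_cc": self.mean_diff_cc,
            "sd_diff_cc": self.sd_diff_cc,
            "iqr_diff_cc": list(self.iqr_diff_cc),
            "prop_over_threshold": self.prop_over_threshold,
            "threshold": self.threshold,
            "n": self.n,
        }


def percent_volume_difference(v_healthy, v_other):
    """Signed percentage difference ``(1 - v_other / v_healthy) * 100``.

    Positive when the other side is smaller than the healthy reference;
    e.g. a reconstructed side of 302 cc against a healthy side of 276 cc
    gives -9.42%, i.e. the reconstructed side is 9.4% larger.
    """
    v_healthy = np.asarray(v_healthy, dtype=float)
    v_other = np.asarray(v_other, dtype=float)
    if np.any(v_healthy <= 0):
        raise ValueError("healthy-side volume must be strictly positive")
    out = (1.0 - v_other / v_healthy) * 100.0
    return float(out) if out.ndim == 0 else out


def volume_difference(v_a, v_b):
    """Absolute volume difference |v_a - v_b| in cc."""
    out = np.abs(np.asarray(v_a, dtype=float) - np.asarray(v_b, dtype=float))
    return float(out) if out.ndim == 0 else out


def asymmetry_summary(
    cohort: Cohort, side_pair: str = "preop", threshold: float = 20.0
) -> AsymmetrySummary:
    """Summarize absolute percentage and cc differences over a cohort.

    ``side_pair`` selects preoperative (healthy vs affected) or postoperative
    (healthy vs reconstructed) volumes.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    if side_pair == "preop":
        ref = cohort.column("v_healthy_pre")
        other = cohort.column("v_affected_pre")
    elif side_pair == "postop":
        ref = cohort.column("v_healthy_post")
        other = cohort.column("v_recon_post")
    else:
        raise ValueError("side_pair must be 'preop' or 'postop'")

    abs_pct = np.abs(percent_volume_difference(ref, other))
    abs_cc = volume_difference(ref, other)
    q25_pct, q75_pct = np.percentile(abs_pct, [25, 75])
    q25_cc, q75_cc = np.percentile(abs_cc, [25, 75])
    return AsymmetrySummary(
        mean_abs_pct=float(np.mean(abs_pct)),
        sd_abs_pct=float(np.std(abs_pct, ddof=1)) if len(cohort) > 1 else 0.0,
        iqr_abs_pct=(float(q25_pct), float(q75_pct)),
        mean_diff_cc=float(np.mean(abs_cc)),
        sd_diff_cc=float(np.std(abs_cc, ddof=1)) if len(cohort) > 1 else 0.0,
        iqr_diff_cc=(float(q25_cc), float(q75_cc)),
        prop_over_threshold=float(np.mean(abs_pct > threshold)),
        threshold=threshold,
        n=len(cohort),
    )
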