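"""Patient-level cohort data model and CSV I/O.

A cohort is a table of unilateral direct-to-implant (DTI) reconstruction
patients. Each record carries the preoperative 3D volumes of the healthy
(contralateral) and affected breasts, the mastectomy specimen weight, the
inserted implant volume, the three-month postoperative 3D volumes of the
reconstructed and healthy breasts, and — once the correction stage has run —
the derived ideal implant volume.

Units are fixed by column: all volumes in cc, specimen weight in g.
Simulated and file-loaded cohorts share this one representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

#: Canonical CSV column order. ``i_ideal`` is written only when populated.
COLUMNS = [
    "patient_id",
    "v_healthy_pre",
    "v_affected_pre",
    "w_mast",
    "i_inserted",
    "v_recon_post",
    "v_healthy_post",
    "i_ideal",
]

#: Measured quantities that must be strictly positive and finite.
MEASURED_COLUMNS = COLUMNS[1:-1]


class CohortValidationError(ValueError):
    """A cohort table violates the data-model invariants."""


class PatientRecord(BaseModel):
    """One patient's volumetric measurements.

    All measured volumes (cc) and the specimen weight (g) must be strictly
    positive and finite. ``i_ideal`` is absent until the correction stage has
    been applied; a corrected volume may legitimately be non-positive in
    extreme cohorts and is therefore not range-restricted.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    v_healthy_pre: float
    v_affected_pre: float
    w_mast: float
    i_inserted: float
    v_recon_post: float
    v_healthy_post: float
    i_ideal: Optional[float] = None

    @field_validator(
        "v_healthy_pre",
        "v_affected_pre",
        "w_mast",
        "i_inserted",
        "v_recon_post",
        "v_healthy_post",
    )
    @classmethod
    def _positive_finite(cls, v: float, info) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError(
                f"{info.field_name} must be strictly positive and finite, got {v!r}"
            )
        return v

    @field_validator("i_ideal")
    @classmethod
    def _finite(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not math.isfinite(v):
            raise ValueError(f"i_ideal must be finite, got {v!r}")
        return v


@dataclass
class Cohort:
    """An ordered collection of :class:`PatientRecord` values.

    Backed by a :class:`pandas.DataFrame` in the canonical column order;
    ``provenance`` is either ``"simulated"`` or the source file path, and
    ``seed`` is set only for simulated cohorts.
    """

    df: pd.DataFrame
    provenance: str = "unknown"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.df = _normalise_frame(self.df)
        _validate_frame(self.df)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PatientRecord]:
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            if "i_ideal" in d and (d["i_ideal"] is None or pd.isna(d["i_ideal"])):
                d["i_ideal"] = None
            yield PatientRecord(**d)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def has_ideal(self) -> bool:
        """True once every record's ideal implant volume has been filled."""
        return "i_ideal" in self.df.columns and self.df["i_ideal"].notna().all()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Sequence[PatientRecord],
        provenance: str = "unknown",
        seed: Optional[int] = None,
    ) -> "Cohort":
        df = pd.DataFrame([r.model_dump() for r in records], columns=COLUMNS)
        return cls(df, provenance=provenance, seed=seed)

    def with_ideal(self, i_ideal: np.ndarray) -> "Cohort":
        """Return a copy whose ``i_ideal`` column is populated."""
        values = np.asarray(i_ideal, dtype=float)
        if values.shape != (len(self),):
            raise ValueError(
                f"i_ideal has length {values.shape}, cohort has {len(self)} records"
            )
        df = self.df.copy()
        df["i_ideal"] = values
        return Cohort(df, provenance=self.provenance, seed=self.seed)

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise KeyError(f"cohort has no column {name!r}")
        return self.df[name].to_numpy(dtype=float)


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "i_ideal" not in df.columns:
        df["i_ideal"] = np.nan
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing column(s): {', '.join(missing)}")
    df = df[COLUMNS].reset_index(drop=True)
    df["patient_id"] = df["patient_id"].astype(str)
    for col in COLUMNS[1:]:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"non-numeric value in column {col!r}: {exc}")
    return df


def _validate_frame(df: pd.DataFrame) -> None:
    ids = df["patient_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate patient_id values: {dupes}")
    for col in MEASURED_COLUMNS:
        vals = df[col]
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"row {row} (patient_id={df['patient_id'].iloc[row]!r}): "
                f"{col} must be strictly positive and finite, got {vals.iloc[row]!r}"
            )
    filled = df["i_ideal"].notna()
    if filled.any() and not np.isfinite(df.loc[filled, "i_ideal"]).all():
        raise CohortValidationError("i_ideal contains non-finite values")


def read_cohort(path: Union[str, Path], strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    The header row must name the canonical columns; ``i_ideal`` may be absent
    or empty. With ``strict=False``, rows violating positivity/finiteness are
    dropped (with their count recorded nowhere — intended for exploratory
    loading only); with ``strict=True`` (default) any invalid row raises
    :class:`CohortValidationError` naming the row and field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not strict:
        df = _normalise_frame(df)
        ok = np.ones(len(df), dtype=bool)
        for col in MEASURED_COLUMNS:
            ok &= np.isfinite(df[col]) & (df[col] > 0)
        ok &= ~df["patient_id"].duplicated()
        df = df[ok]
    return Cohort(df, provenance=str(path))


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> Path:
    """Write a cohort CSV in the canonical column order.

    The ``i_ideal`` column is included only when at least one record has a
    corrected volume; missing values are written as empty cells, never 0.
    """
    path = Path(path)
    df = cohort.df
    if df["i_ideal"].isna().all():
        df = df.drop(columns=["i_ideal"])
    df.to_csv(path, index=False, float_format="%.10g")
    return path
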