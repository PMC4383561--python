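"""Cohort reading/writing, case-cohort reweighting, risk classification,
and descriptive summaries.

A cohort is carried as a :class:`pandas.DataFrame` with one row per
patient and the canonical CSV columns ``patient_id, cohort, age_at_rp,
risk5, risk5_lo, risk5_hi, is_control, weight``.  ``risk5`` is the
genomic-classifier-predicted 5-year probability of metastasis with its
95% CI in ``risk5_lo`` / ``risk5_hi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "DEFAULT_RISK_THRESHOLD",
    "CohortValidationError",
    "PatientRecord",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "reweight_cohort",
    "classify_risk",
    "cohort_summary",
]

COHORT_COLUMNS = [
    "patient_id",
    "cohort",
    "age_at_rp",
    "risk5",
    "risk5_lo",
    "risk5_hi",
    "is_control",
    "weight",
]

#: 5-year metastasis risk above which a patient is classed as high risk
#: (the published physician-recommendation threshold).
DEFAULT_RISK_THRESHOLD = 0.06


class CohortValidationError(ValueError):
    """A cohort file or frame violates the schema; rows are named."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject of the simulation cohort."""

    patient_id: str
    age_at_rp: float
    risk5: float
    risk5_lo: float
    risk5_hi: float
    cohort: str = "synthetic"
    weight: int = 1
    is_control: bool = False

    def validate(self) -> "PatientRecord":
        if not (0.0 <= self.risk5_lo <= self.risk5 <= self.risk5_hi <= 1.0):
            raise CohortValidationError(
                f"patient {self.patient_id}: risk CI ordering violated "
                f"({self.risk5_lo}, {self.risk5}, {self.risk5_hi})"
            )
        if self.age_at_rp <= 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: non-positive age {self.age_at_rp}"
            )
        if self.weight < 1:
            raise CohortValidationError(
                f"patient {self.patient_id}: weight {self.weight} < 1"
            )
        return self


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort frame; offending rows are reported by row number."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    problems = []
    risk = df["risk5"].to_numpy(float)
    lo = df["risk5_lo"].to_numpy(float)
    hi = df["risk5_hi"].to_numpy(float)
    age = df["age_at_rp"].to_numpy(float)
    weight = df["weight"].to_numpy()
    bad_range = (risk < 0) | (risk > 1) | (lo < 0) | (hi > 1)
    bad_order = (lo > risk) | (risk > hi)
    bad_age = age <= 0
    bad_weight = weight < 1
    for idx in np.flatnonzero(bad_range):
        problems.append(f"row {idx}: risk outside [0, 1]")
    for idx in np.flatnonzero(bad_order & ~bad_range):
        problems.append(f"row {idx}: risk CI ordering violated")
    for idx in np.flatnonzero(bad_age):
        problems.append(f"row {idx}: non-positive age")
    for idx in np.flatnonzero(bad_weight):
        problems.append(f"row {idx}: weight < 1")
    if problems:
        raise CohortValidationError("; ".join(problems))
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (comma, UTF-8, header row)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns: {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    df["weight"] = df["weight"].astype(int)
    validate_cohort(df)
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df)
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)


def reweight_cohort(df: pd.DataFrame, control_weight: int) -> pd.DataFrame:
    """Expand controls of a case-cohort sample by replication.

    Each control row is repeated ``control_weight`` times and each case
    appears once, in stable input order; ``weight`` is set to 1 on every
    output row because the multiplicity is realized by replication.  The
    expanded frame therefore has ``n_cases + control_weight * n_controls``
    rows and downstream samplers need no weighted-draw logic.
    """
    if "is_control" not in df.columns:
        raise CohortValidationError("reweighting requires an is_control column")
    if control_weight < 1:
        raise ValueError("control_weight must be a positive integer")
    if control_weight == 1:
        return df.copy().reset_index(drop=True)
    reps = np.where(df["is_control"].to_numpy(bool), control_weight, 1)
    out = df.loc[df.index.repeat(reps)].copy()
    out["weight"] = 1
    return out.reset_index(drop=True)


def classify_risk(risk5, threshold: float = DEFAULT_RISK_THRESHOLD):
    """Classify 5-year metastasis risk as ``"high"`` or ``"low"``.

    The comparison is strict: risk must exceed the threshold to be high,
    so a risk exactly at 6% is low.  Accepts a scalar, an array, or a
    :class:`PatientRecord`.
    """
    if isinstance(risk5, PatientRecord):
        risk5 = risk5.risk5
    arr = np.asarray(risk5, dtype=float)
    out = np.where(arr > threshold, "high", "low")
    return out.item() if out.ndim == 0 else out


def cohort_summary(
    df: pd.DataFrame, threshold: float = DEFAULT_RISK_THRESHOLD
) -> dict:
    """Weighted descriptive summary of a cohort.

    Returns weighted mean/SD of age, weighted mean risk, the risk range,
    and the weighted proportion classified high risk at ``threshold``.
    """
    if len(df) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    w = df["weight"].to_numpy(float)
    age = df["age_at_rp"].to_numpy(float)
    risk = df["risk5"].to_numpy(float)
    wsum = w.sum()
    age_mean = float(np.average(age, weights=w))
    age_var = float(np.average((age - age_mean) ** 2, weights=w))
    n_eff = wsum
    age_sd = float(np.sqrt(age_var * n_eff / (n_eff - 1))) if n_eff > 1 else 0.0
    return {
        "n_records": int(len(df)),
        "n_weighted": float(wsum),
        "age_mean": age_mean,
        "age_sd": age_sd,
        "risk_mean": float(np.average(risk, weights=w)),
        "risk_min": float(risk.min()),
        "risk_max": float(risk.max()),
        "high_risk_proportion": float(
            np.average(risk > threshold, weights=w)
        ),
        "threshold": float(threshold),
    }
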