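"""Model parameter containers, validation, and probability transforms.

The decision model is a monthly-cycle state-transition microsimulation of
men after radical prostatectomy (RP).  All event probabilities stored here
are *monthly* probabilities; literature inputs quoted over longer periods
are converted with the constant-hazard identity in
:func:`to_monthly_probability`.  Utilities are preference weights in (0, 1]
that combine multiplicatively across health state, active treatment, and
active complications.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "TransitionBlock",
    "Complication",
    "Utilities",
    "Durations",
    "LifeTable",
    "ModelParams",
    "PolicyTable",
    "MODALITIES",
    "POLICY_ARMS",
    "POLICY_CONTEXTS",
    "to_monthly_probability",
    "other_cause_monthly_prob",
    "load_params",
    "save_params",
    "default_params",
    "default_policy",
    "default_life_table",
    "get_param",
    "set_param",
]

MODALITIES = ("observation", "rt", "ht", "rt_ht")
POLICY_ARMS = ("usual_care", "gc_low", "gc_high")
POLICY_CONTEXTS = ("adjuvant", "salvage")

_SIMPLEX_TOL = 1e-9


class ParameterError(ValueError):
    """A model parameter failed validation; the message names the field."""


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} = {value!r} is not a probability in [0, 1]")


def _check_utility(value: float, name: str) -> None:
    if not (0.0 < value <= 1.0):
        raise ParameterError(f"{name} = {value!r} is not a utility in (0, 1]")


@dataclass
class TransitionBlock:
    """Monthly disease-progression probabilities for one treatment history.

    Attributes
    ----------
    bcr_from_ned : float
        Monthly probability of biochemical recurrence (BCR) while NED.
    met_from_ned : float
        Monthly probability of metastasis (MET) directly from NED.
    met_from_bcr : float
        Monthly probability of MET while in the BCR state.
    """

    bcr_from_ned: float
    met_from_ned: float
    met_from_bcr: float

    def validate(self, prefix: str) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f"{prefix}.{f.name}")
        # outgoing probabilities from NED within one cycle
        if self.bcr_from_ned + self.met_from_ned > 1.0 + _SIMPLEX_TOL:
            raise ParameterError(
                f"{prefix}: bcr_from_ned + met_from_ned exceeds 1"
            )


@dataclass
class Complication:
    """A treatment-attributable complication.

    ``duration_months=None`` means the complication persists for the
    remainder of the treatment course that caused it.
    """

    onset_monthly: float
    utility: float
    duration_months: int | None = None

    def validate(self, prefix: str) -> None:
        _check_prob(self.onset_monthly, f"{prefix}.onset_monthly")
        _check_utility(self.utility, f"{prefix}.utility")
        if self.duration_months is not None and self.duration_months < 0:
            raise ParameterError(f"{prefix}.duration_months must be >= 0")


@dataclass
class Utilities:
    """Health-state and treatment-state utility weights."""

    ned: float
    bcr: float
    met: float
    rt: float
    ht: float
    rt_ht: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_utility(getattr(self, f.name), f"utilities.{f.name}")


@dataclass
class Durations:
    """Treatment course lengths in months."""

    radiation_months: int = 2
    adjuvant_hormone_months: int = 6
    salvage_hormone_months: int = 6
    recurrence_hormone_months: int = 24

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"durations.{f.name} must be >= 0")


class LifeTable:
    """Age-indexed annual probability of death from causes other than
    prostate cancer.

    Ages outside the table are clamped to the nearest tabulated age, so a
    simulated patient older than the last row keeps the last row's rate.
    """

    def __init__(self, ages: np.ndarray, annual_qx: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        annual_qx = np.asarray(annual_qx, dtype=float)
        if ages.size == 0:
            raise ParameterError("life table is empty")
        if ages.size != annual_qx.size:
            raise ParameterError("life table ages and qx differ in length")
        if np.any(np.diff(ages) != 1):
            raise ParameterError("life table ages must be consecutive integers")
        if np.any((annual_qx < 0) | (annual_qx > 1)):
            raise ParameterError("life table qx values must lie in [0, 1]")
        self.ages = ages
        self.annual_qx = annual_qx
        # precomputed monthly probabilities under a constant hazard in-year
        self.monthly_qx = to_monthly_probability(annual_qx, 12)

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def annual(self, age: float) -> float:
        idx = int(np.clip(int(np.floor(age)) - self.age_min, 0, self.ages.size - 1))
        return float(self.annual_qx[idx])

    def monthly(self, age: float) -> float:
        idx = int(np.clip(int(np.floor(age)) - self.age_min, 0, self.ages.size - 1))
        return float(self.monthly_qx[idx])

    def monthly_vector(self, ages: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.floor(ages).astype(int) - self.age_min, 0, self.ages.size - 1
        )
        return self.monthly_qx[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_qx": self.annual_qx})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        missing = {"age", "annual_qx"} - set(df.columns)
        if missing:
            raise ParameterError(f"life table missing columns: {sorted(missing)}")
        return cls(df["age"].to_numpy(), df["annual_qx"].to_numpy())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.annual_qx, other.annual_qx)
        )


@dataclass
class ModelParams:
    """Complete parameter set for the microsimulation.

    ``transitions`` holds one :class:`TransitionBlock` per treatment
    history (``"untreated"`` and ``"treated"``); adjuvant or salvage
    therapy moves a patient permanently onto the treated block, which is
    how the treatment effect on progression enters the model.
    """

    transitions: dict[str, TransitionBlock]
    pc_death_from_met: float
    salvage_success_monthly: float
    complications: dict[str, Complication]
    utilities: Utilities
    durations: Durations
    life_table: LifeTable
    cycle_length_months: int = 1
    horizon_months: int = 120
    discount_rate: float = 0.0

    def validate(self) -> "ModelParams":
        for key in ("untreated", "treated"):
            if key not in self.transitions:
                raise ParameterError(f"transitions missing block {key!r}")
            self.transitions[key].validate(f"transitions.{key}")
        _check_prob(self.pc_death_from_met, "pc_death_from_met")
        _check_prob(self.salvage_success_monthly, "salvage_success_monthly")
        for key in ("radiation", "hormone"):
            if key not in self.complications:
                raise ParameterError(f"complications missing entry {key!r}")
            self.complications[key].validate(f"complications.{key}")
        self.utilities.validate()
        self.durations.validate()
        if self.horizon_months <= 0:
            raise ParameterError("horizon_months must be positive")
        if self.cycle_length_months != 1:
            raise ParameterError("only 1-month cycles are supported")
        if self.discount_rate != 0.0:
            raise ParameterError("only undiscounted outcomes are supported")
        return self

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cycle_length_months": self.cycle_length_months,
            "horizon_months": self.horizon_months,
            "discount_rate": self.discount_rate,
            "transitions": {
                k: dataclasses.asdict(v) for k, v in sorted(self.transitions.items())
            },
            "pc_death_from_met": self.pc_death_from_met,
            "salvage_success_monthly": self.salvage_success_monthly,
            "complications": {
                k: dataclasses.asdict(v)
                for k, v in sorted(self.complications.items())
            },
            "utilities": dataclasses.asdict(self.utilities),
            "durations": dataclasses.asdict(self.durations),
            "life_table": {
                "age": self.life_table.ages.tolist(),
                "annual_qx": self.life_table.annual_qx.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        required = [
            "transitions",
            "pc_death_from_met",
            "salvage_success_monthly",
            "complications",
            "utilities",
            "durations",
            "life_table",
        ]
        missing = [k for k in required if k not in d]
        if missing:
            raise ParameterError(f"config missing sections: {missing}")
        lt = d["life_table"]
        params = cls(
            transitions={
                k: TransitionBlock(**v) for k, v in d["transitions"].items()
            },
            pc_death_from_met=float(d["pc_death_from_met"]),
            salvage_success_monthly=float(d["salvage_success_monthly"]),
            complications={
                k: Complication(**v) for k, v in d["complications"].items()
            },
            utilities=Utilities(**d["utilities"]),
            durations=Durations(**d["durations"]),
            life_table=LifeTable(np.asarray(lt["age"]), np.asarray(lt["annual_qx"])),
            cycle_length_months=int(d.get("cycle_length_months", 1)),
            horizon_months=int(d.get("horizon_months", 120)),
            discount_rate=float(d.get("discount_rate", 0.0)),
        )
        return params.validate()


class PolicyTable:
    """Treatment-decision probabilities.

    One probability row over the modalities ``(observation, rt, ht,
    rt_ht)`` for every decision context (``adjuvant`` at model entry,
    ``salvage`` at first BCR for previously untreated patients) and every
    arm (``usual_care``, and ``gc_low`` / ``gc_high`` for
    genomic-classifier-guided care, selected by the patient's risk class).
    """

    def __init__(self, rows: dict[tuple[str, str], dict[str, float]]):
        self.rows = {k: dict(v) for k, v in rows.items()}
        self.validate()

    def validate(self) -> "PolicyTable":
        for context in POLICY_CONTEXTS:
            for arm in POLICY_ARMS:
                key = (context, arm)
                if key not in self.rows:
                    raise ParameterError(f"policy missing row {context}/{arm}")
                row = self.rows[key]
                missing = set(MODALITIES) - set(row)
                if missing:
                    raise ParameterError(
                        f"policy row {context}/{arm} missing modalities "
                        f"{sorted(missing)}"
                    )
                for m in MODALITIES:
                    _check_prob(row[m], f"policy.{context}.{arm}.{m}")
                total = sum(row[m] for m in MODALITIES)
                if abs(total - 1.0) > _SIMPLEX_TOL:
                    raise ParameterError(
                        f"policy row {context}/{arm} sums to {total!r}, not 1"
                    )
        return self

    def row(self, context: str, arm: str) -> dict[str, float]:
        return dict(self.rows[(context, arm)])

    def row_vector(self, context: str, arm: str) -> np.ndarray:
        row = self.rows[(context, arm)]
        return np.array([row[m] for m in MODALITIES], dtype=float)

    def replace_row(
        self, context: str, arm: str, row: dict[str, float]
    ) -> "PolicyTable":
        rows = {k: dict(v) for k, v in self.rows.items()}
        rows[(context, arm)] = dict(row)
        return PolicyTable(rows)

    def copy(self) -> "PolicyTable":
        return PolicyTable(self.rows)

    def to_dict(self) -> dict:
        out: dict = {}
        for context in POLICY_CONTEXTS:
            out[context] = {
                arm: {m: self.rows[(context, arm)][m] for m in MODALITIES}
                for arm in POLICY_ARMS
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PolicyTable":
        rows = {}
        for context in POLICY_CONTEXTS:
            if context not in d:
                raise ParameterError(f"policy config missing context {context!r}")
            for arm in POLICY_ARMS:
                if arm not in d[context]:
                    raise ParameterError(f"policy config missing arm {context}/{arm}")
                rows[(context, arm)] = {
                    m: float(p) for m, p in d[context][arm].items()
                }
        return cls(rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, PolicyTable) and self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# probability transforms


def to_monthly_probability(p, n_months):
    """Convert a probability over ``n_months`` months to a monthly one.

    Uses the constant-hazard identity ``m = 1 - (1 - p)**(1/n)``, so that
    ``(1 - m)**n == 1 - p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("probability must lie in [0, 1]")
    if n_months < 1:
        raise ParameterError("n_months must be >= 1")
    out = 1.0 - (1.0 - p) ** (1.0 / n_months)
    return float(out) if out.ndim == 0 else out


def other_cause_monthly_prob(age: float, life_table: LifeTable) -> float:
    """Monthly probability of death from other causes at a given age.

    The annual rate for the patient's current integer age is looked up
    (clamped to the table's range) and converted to a monthly probability.
    """
    if age <= 0:
        raise ParameterError("age must be positive")
    return life_table.monthly(age)


# ---------------------------------------------------------------------------
# config IO


def load_params(path: str | Path) -> tuple[ModelParams, PolicyTable]:
    """Load and validate a YAML/JSON model configuration.

    The config has sections ``transitions``, ``pc_death_from_met``,
    ``salvage_success_monthly``, ``complications``, ``utilities``,
    ``durations``, ``policies``, and either an inline ``life_table`` or a
    ``life_table_path`` CSV (columns ``age``, ``annual_qx``) resolved
    relative to the config file.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError(f"config {path} is not a mapping")
    if "life_table" not in doc:
        lt_path = doc.get("life_table_path")
        if lt_path is None:
            raise ParameterError("config needs life_table or life_table_path")
        lt_file = (path.parent / lt_path).resolve()
        df = pd.read_csv(lt_file)
        doc = dict(doc)
        doc["life_table"] = {
            "age": df["age"].tolist(),
            "annual_qx": df["annual_qx"].tolist(),
        }
    if "policies" not in doc:
        raise ParameterError("config missing sections: ['policies']")
    params = ModelParams.from_dict(doc)
    policy = PolicyTable.from_dict(doc["policies"])
    return params, policy


def save_params(
    params: ModelParams, policy: PolicyTable, path: str | Path
) -> None:
    """Serialize a configuration back to YAML (inline life table)."""
    doc = params.to_dict()
    doc["policies"] = policy.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# shipped defaults


def default_life_table() -> LifeTable:
    """Stylized synthetic male all-cause life table (ages 40-100).

    A Gompertz curve ``q(x) = a * exp(b * x)`` anchored to recent US male
    all-cause mortality magnitudes.  This is a synthetic stand-in with the
    right shape and scale; substitute a national life table CSV for
    applied work.
    """
    ages = np.arange(40, 101)
    qx = np.minimum(5.0e-5 * np.exp(0.0875 * ages), 1.0)
    return LifeTable(ages, qx)


def default_params() -> ModelParams:
    """The shipped baseline parameter set.

    Magnitudes are plausible for the post-prostatectomy setting (monthly
    progression probabilities well below 1, a roughly 50% untreated 5-year
    BCR risk, a ~7-11% 5-year metastasis risk, multi-year survival with
    metastatic disease) but are a testing fixture, not a transcription of
    any published input table.
    """
    return ModelParams(
        transitions={
            "untreated": TransitionBlock(
                bcr_from_ned=0.0105, met_from_ned=0.0012, met_from_bcr=0.0055
            ),
            "treated": TransitionBlock(
                bcr_from_ned=0.0050, met_from_ned=0.0007, met_from_bcr=0.0035
            ),
        },
        pc_death_from_met=0.020,
        salvage_success_monthly=0.12,
        complications={
            "radiation": Complication(onset_monthly=0.05, utility=0.85),
            "hormone": Complication(onset_monthly=0.03, utility=0.88),
        },
        utilities=Utilities(ned=0.92, bcr=0.83, met=0.45, rt=0.90, ht=0.85, rt_ht=0.78),
        durations=Durations(),
        life_table=default_life_table(),
    ).validate()


def default_policy() -> PolicyTable:
    """The shipped baseline treatment-decision table.

    Usual care sends roughly half of patients to observation; guided care
    is more aggressive for high-risk patients (5-year metastasis risk
    above the 6% threshold) and more conservative for low-risk patients,
    mirroring the direction of published physician-recommendation shifts
    under genomic-classifier results.
    """
    return PolicyTable(
        {
            ("adjuvant", "usual_care"): {
                "observation": 0.55, "rt": 0.25, "ht": 0.10, "rt_ht": 0.10,
            },
            ("adjuvant", "gc_low"): {
                "observation": 0.85, "rt": 0.08, "ht": 0.04, "rt_ht": 0.03,
            },
            ("adjuvant", "gc_high"): {
                "observation": 0.25, "rt": 0.40, "ht": 0.15, "rt_ht": 0.20,
            },
            ("salvage", "usual_care"): {
                "observation": 0.35, "rt": 0.35, "ht": 0.15, "rt_ht": 0.15,
            },
            ("salvage", "gc_low"): {
                "observation": 0.55, "rt": 0.30, "ht": 0.07, "rt_ht": 0.08,
            },
            ("salvage", "gc_high"): {
                "observation": 0.10, "rt": 0.45, "ht": 0.20, "rt_ht": 0.25,
            },
        }
    )


def shipped_config_path() -> Path:
    """Path to the packaged default YAML config."""
    return Path(resources.files("gcsim").joinpath("data/default_params.yaml"))


# ---------------------------------------------------------------------------
# dotted-path access (used by the sensitivity analyses)


def get_param(params: ModelParams, path: str) -> float:
    """Read a scalar parameter by dotted path.

    e.g. ``"transitions.untreated.bcr_from_ned"``, ``"utilities.ned"``,
    ``"pc_death_from_met"``, ``"complications.radiation.onset_monthly"``.
    """
    obj: object = params
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise ParameterError(f"no parameter at path {path!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ParameterError(f"no parameter at path {path!r}")
            obj = getattr(obj, part)
    if not isinstance(obj, (int, float)):
        raise ParameterError(f"path {path!r} does not point at a scalar")
    return float(obj)


def set_param(params: ModelParams, path: str, value: float) -> ModelParams:
    """Return a copy of ``params`` with the value at ``path`` replaced."""
    new = params.copy()
    parts = path.split(".")
    obj: object = new
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ParameterError(f"no parameter at path {path!r}")
        obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise ParameterError(f"no parameter at path {path!r}")
        setattr(obj, leaf, value)
    return new.validate()
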