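"""Synthetic cohort and parameter-fixture generation.

Real genomic-classifier validation cohorts are small tables of (age at
prostatectomy, 5-year metastasis risk with 95% CI, case/control status).
This module generates cohorts with the same statistical structure —
truncated-normal ages and right-skewed beta-distributed risks calibrated
to a target mean and high-risk tail fraction — so every downstream stage
of the pipeline can be exercised and tested without the deposited files.

:func:`reference_cohort` additionally provides two fully calibrated
synthetic stand-ins whose reweighted summary statistics reproduce the
published validation-cohort margins (sample sizes, mean risk, risk range,
and high-risk share) exactly, by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

import pandas as pd

from .cohort_io import COHORT_COLUMNS, DEFAULT_RISK_THRESHOLD, validate_cohort
from .parameters import (
    Complication,
    ModelParams,
    TransitionBlock,
    Utilities,
    default_params,
)

__all__ = [
    "CohortSpec",
    "BetaCalibrationError",
    "solve_beta_parameters",
    "generate_cohort",
    "reference_cohort",
    "generate_param_fixture",
]

AGE_TRUNCATION = (40.0, 90.0)  # years; keeps life-table lookups plausible


class BetaCalibrationError(ValueError):
    """No beta distribution satisfies the requested (mean, tail) pair."""


@dataclass(frozen=True)
class CohortSpec:
    """Target statistical structure of a synthetic cohort.

    ``high_risk_fraction`` is the desired share of patients whose 5-year
    metastasis risk exceeds ``threshold``; together with ``risk_mean`` it
    pins down the two parameters of the beta risk distribution.
    """

    n_patients: int
    age_mean: float = 63.28
    age_sd: float = 7.26
    risk_mean: float = 0.076
    risk_min: float = 0.0095
    risk_max: float = 0.48
    high_risk_fraction: float = 0.4146
    threshold: float = DEFAULT_RISK_THRESHOLD
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (0.0 <= self.risk_min < self.risk_mean < self.risk_max <= 1.0):
            raise ValueError(
                "need 0 <= risk_min < risk_mean < risk_max <= 1, got "
                f"({self.risk_min}, {self.risk_mean}, {self.risk_max})"
            )
        if not (0.0 <= self.high_risk_fraction <= 1.0):
            raise ValueError("high_risk_fraction must lie in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        return self


def solve_beta_parameters(
    mean: float, threshold: float, frac_above: float
) -> tuple[float, float]:
    """Find beta parameters with the given mean and tail mass.

    Fixing the mean ties ``b = a (1 - mean) / mean``; the remaining shape
    parameter is found by root-finding on ``P(X > threshold)``, which runs
    monotonically from ``mean`` (the two-point limit ``a -> 0``) to 1 or 0
    (the point-mass limit ``a -> inf``, depending on the side of the mean
    the threshold falls on).  Raises :class:`BetaCalibrationError` when the
    requested pair is outside that attainable range.
    """
    if not (0.0 < mean < 1.0):
        raise BetaCalibrationError(f"mean {mean} must lie strictly in (0, 1)")
    if not (0.0 < threshold < 1.0):
        raise BetaCalibrationError(f"threshold {threshold} must lie in (0, 1)")

    def tail(log_a: float) -> float:
        a = np.exp(log_a)
        b = a * (1.0 - mean) / mean
        return stats.beta.sf(threshold, a, b) - frac_above

    lo, hi = -8.0, 10.0
    f_lo, f_hi = tail(lo), tail(hi)
    if f_lo == 0.0:
        a = np.exp(lo)
    elif f_hi == 0.0:
        a = np.exp(hi)
    elif np.sign(f_lo) == np.sign(f_hi):
        raise BetaCalibrationError(
            f"no beta distribution has mean {mean} and "
            f"P(X > {threshold}) = {frac_above}"
        )
    else:
        a = np.exp(optimize.brentq(tail, lo, hi, xtol=1e-12))
    return float(a), float(a * (1.0 - mean) / mean)


def _truncated_normal_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    lo, hi = AGE_TRUNCATION
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)


def _assemble(
    ids, cohort_label, ages, risks, is_control, ci_rel_width
) -> pd.DataFrame:
    risks = np.asarray(risks, dtype=float)
    df = pd.DataFrame(
        {
            "patient_id": ids,
            "cohort": cohort_label,
            "age_at_rp": np.round(np.asarray(ages, dtype=float), 2),
            "risk5": risks,
            "risk5_lo": np.clip(risks * (1.0 - ci_rel_width), 0.0, 1.0),
            "risk5_hi": np.clip(risks * (1.0 + ci_rel_width), 0.0, 1.0),
            "is_control": np.asarray(is_control, dtype=bool),
            "weight": 1,
        },
        columns=COHORT_COLUMNS,
    )
    return validate_cohort(df)


def generate_cohort(
    spec: CohortSpec,
    cohort_label: str = "synthetic",
    ci_rel_width: float = 0.4,
) -> pd.DataFrame:
    """Draw a synthetic cohort matching a :class:`CohortSpec`.

    Ages come from a normal truncated to 40-90 years; risks from the
    calibrated beta distribution, clipped to ``[risk_min, risk_max]``.
    Per-patient 95% CI bounds are placed at ``risk5 * (1 ± ci_rel_width)``
    and clipped to [0, 1].  Identical seeds yield identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    a, b = solve_beta_parameters(
        spec.risk_mean, spec.threshold, spec.high_risk_fraction
    )
    ages = _truncated_normal_ages(rng, n, spec.age_mean, spec.age_sd)
    risks = np.clip(rng.beta(a, b, size=n), spec.risk_min, spec.risk_max)
    ids = [f"{cohort_label}-{i:05d}" for i in range(n)]
    return _assemble(ids, cohort_label, ages, risks, False, ci_rel_width)


# ---------------------------------------------------------------------------
# calibrated reference cohorts


@dataclass(frozen=True)
class _ReferenceSpec:
    n_cases: int
    n_controls: int          # 0 => plain cohort, no reweighting intended
    control_weight: int
    high_cases: int
    high_controls: int
    risk_mean_weighted: float
    risk_min: float
    risk_max: float
    age_mean: float
    age_sd: float


_REFERENCE = {
    # 68 cases + 148 controls; expanding controls x5 gives 808 records of
    # which 35 + 5*60 = 335 (41.46%) are high risk at the 6% threshold.
    "mayo": _ReferenceSpec(
        n_cases=68, n_controls=148, control_weight=5,
        high_cases=35, high_controls=60,
        risk_mean_weighted=0.076, risk_min=0.0095, risk_max=0.48,
        age_mean=63.28, age_sd=7.26,
    ),
    # 139 patients, no case-control structure; 63/139 = 45.32% high risk.
    "tju": _ReferenceSpec(
        n_cases=139, n_controls=0, control_weight=1,
        high_cases=63, high_controls=0,
        risk_mean_weighted=0.071, risk_min=0.0097, risk_max=0.32,
        age_mean=60.71, age_sd=7.24,
    ),
}


def _truncated_beta(
    rng: np.random.Generator, n: int, a: float, b: float, lo: float, hi: float
) -> np.ndarray:
    u_lo, u_hi = stats.beta.cdf([lo, hi], a, b)
    u = rng.uniform(u_lo, u_hi, size=n)
    return stats.beta.ppf(u, a, b)


def reference_cohort(name: str, seed: int = 0, ci_rel_width: float = 0.4):
    """Synthetic stand-in for a deposited validation cohort.

    ``name`` is ``"mayo"`` (case-cohort sample: 68 cases + 148 controls,
    control weight 5) or ``"tju"`` (139 patients).  The generated risks
    are drawn from the calibrated beta distribution and then adjusted so
    the *expanded* cohort reproduces the published margins exactly: the
    weighted mean risk, the weighted high-risk share at the 6% threshold,
    and the risk range (the extreme records are pinned to the published
    minimum and maximum).

    Returns ``(cohort, control_weight)``; apply
    :func:`gcsim.cohort_io.reweight_cohort` with that weight to obtain the
    simulation cohort.
    """
    try:
        ref = _REFERENCE[name]
    except KeyError:
        raise ValueError(f"unknown reference cohort {name!r}") from None
    rng = np.random.default_rng(seed)
    thr = DEFAULT_RISK_THRESHOLD
    a, b = solve_beta_parameters(ref.risk_mean_weighted, thr, 0.41)

    n_low_cases = ref.n_cases - ref.high_cases
    n_low_ctrl = ref.n_controls - ref.high_controls

    # draw class-conditional risks; keep head-room for the calibration scale
    low_hi = thr - 1e-4
    high_lo = thr + 1e-4
    high_cap = ref.risk_max * 0.80
    low_vals = _truncated_beta(
        rng, n_low_cases + n_low_ctrl, a, b, ref.risk_min, low_hi
    )
    high_vals = _truncated_beta(
        rng, ref.high_cases + ref.high_controls, a, b, high_lo, high_cap
    )

    # pin the published range: one low record at the minimum (a control when
    # available, so the pin survives reweighting unchanged), one high case
    # at the maximum
    low_vals[0] = ref.risk_min
    high_vals[0] = ref.risk_max

    # weights of each record in the expanded cohort
    w_low = np.concatenate(
        [np.ones(n_low_cases), np.full(n_low_ctrl, ref.control_weight)]
    )
    w_high = np.concatenate(
        [np.ones(ref.high_cases), np.full(ref.high_controls, ref.control_weight)]
    )

    n_expanded = ref.n_cases + ref.control_weight * ref.n_controls
    target_sum = ref.risk_mean_weighted * n_expanded
    fixed_sum = float(np.dot(w_low, low_vals)) + ref.risk_max * w_high[0]

    # affine rescale of the adjustable high risks about the threshold so
    # the expanded weighted mean is exact; values the rescale would push
    # past a safety cap are clipped there and the remainder re-solved,
    # keeping every value strictly inside (threshold, risk_max)
    adj_vals = high_vals[1:].copy()
    adj_w = w_high[1:]
    pivot = high_lo
    cap = ref.risk_max * 0.95
    need_total = target_sum - fixed_sum
    free = np.ones(adj_vals.size, dtype=bool)
    for _ in range(adj_vals.size + 1):
        w_free = adj_w[free]
        v_free = adj_vals[free]
        need = need_total - float(np.dot(adj_w[~free], adj_vals[~free]))
        have = float(np.dot(w_free, v_free - pivot))
        if have <= 0:
            raise BetaCalibrationError(
                f"reference cohort {name!r}: calibration infeasible"
            )
        gamma = (need - pivot * w_free.sum()) / have
        if gamma <= 0:
            raise BetaCalibrationError(
                f"reference cohort {name!r}: calibration infeasible "
                f"(gamma={gamma})"
            )
        scaled = pivot + gamma * (v_free - pivot)
        if scaled.max() < cap:
            adj_vals[free] = scaled
            break
        # pin the largest value at the cap and re-solve for the rest
        worst = np.flatnonzero(free)[np.argmax(v_free)]
        adj_vals[worst] = cap
        free[worst] = False
        if not free.any():
            raise BetaCalibrationError(
                f"reference cohort {name!r}: calibration infeasible (all "
                "values at cap)"
            )
    high_vals = np.concatenate([[ref.risk_max], adj_vals])

    risks = np.empty(ref.n_cases + ref.n_controls)
    is_control = np.zeros(risks.size, dtype=bool)
    # cases first (high then low), then controls (high then low)
    risks[: ref.high_cases] = high_vals[: ref.high_cases]
    risks[ref.high_cases : ref.n_cases] = low_vals[:n_low_cases]
    risks[ref.n_cases : ref.n_cases + ref.high_controls] = high_vals[
        ref.high_cases :
    ]
    risks[ref.n_cases + ref.high_controls :] = low_vals[n_low_cases:]
    is_control[ref.n_cases :] = True

    ages = _truncated_normal_ages(rng, risks.size, ref.age_mean, ref.age_sd)
    ids = [f"{name}-{i:04d}" for i in range(risks.size)]
    cohort = _assemble(ids, name, ages, risks, is_control, ci_rel_width)
    return cohort, ref.control_weight


# ---------------------------------------------------------------------------
# parameter fixtures


def generate_param_fixture(seed: int = 0) -> ModelParams:
    """A complete, internally consistent ModelParams fixture.

    Starts from the shipped baseline and applies a seed-deterministic
    jitter (probabilities x U(0.9, 1.1), utilities x U(0.97, 1.03), both
    clipped to their valid ranges) so different seeds give distinct but
    always-valid parameter sets.
    """
    rng = np.random.default_rng(seed)
    base = default_params()

    def jp(p: float) -> float:  # jitter a probability
        return float(np.clip(p * rng.uniform(0.9, 1.1), 0.0, 0.999))

    def ju(u: float) -> float:  # jitter a utility
        return float(np.clip(u * rng.uniform(0.97, 1.03), 1e-6, 1.0))

    transitions = {
        k: TransitionBlock(
            bcr_from_ned=jp(v.bcr_from_ned),
            met_from_ned=jp(v.met_from_ned),
            met_from_bcr=jp(v.met_from_bcr),
        )
        for k, v in base.transitions.items()
    }
    complications = {
        k: Complication(
            onset_monthly=jp(v.onset_monthly),
            utility=ju(v.utility),
            duration_months=v.duration_months,
        )
        for k, v in base.complications.items()
    }
    utilities = Utilities(
        **{
            f.name: ju(getattr(base.utilities, f.name))
            for f in dataclasses.fields(Utilities)
        }
    )
    return ModelParams(
        transitions=transitions,
        pc_death_from_met=jp(base.pc_death_from_met),
        salvage_success_monthly=jp(base.salvage_success_monthly),
        complications=complications,
        utilities=utilities,
        durations=base.durations,
        life_table=base.life_table,
        horizon_months=base.horizon_months,
    ).validate()
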