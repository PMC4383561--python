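"""Monthly-cycle state-transition microsimulation engine.

Health states are NED (no evidence of disease after prostatectomy), BCR
(biochemical recurrence), MET (metastatic disease), and two absorbing
death states (prostate-cancer death, other-cause death).  Each simulated
month a patient accrues utility for the cycle and then at most one
transition fires, drawn in a fixed order: other-cause death, prostate-
cancer death (MET only), MET onset, BCR onset, and finally redistribution
back to NED for patients on an active salvage course.

Two execution routes share identical semantics and identical random-number
consumption.  All uniforms are pre-drawn into a :class:`DrawSet`, indexed
by (patient, month, event channel); because draws are addressed by
counter rather than consumed sequentially, two treatment arms evaluated
on the same DrawSet are exactly paired (common random numbers), and the
scalar reference route (:func:`step_cycle` / :func:`simulate_patient`)
is bit-identical to the vectorized cohort route
(:func:`simulate_cohort`) used by the bootstrap comparison.

Timing convention: utility accrues for a cycle, then the transition at
its end takes effect, so death drawn in cycle k leaves the patient with
k months of life-years.  No half-cycle correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import DEFAULT_RISK_THRESHOLD, PatientRecord
from .parameters import MODALITIES, ModelParams, PolicyTable
from . import stats as _stats
from .stats import OCCUPANCY_BUCKETS, STATE_NAMES

__all__ = [
    "NED", "BCR", "MET", "DEATH_PC", "DEATH_OC",
    "STATE_NAMES", "OCCUPANCY_BUCKETS",
    "DrawSet", "PatientDraws", "TreatmentState", "Trajectory",
    "CohortOutcomes", "Arm", "ComparisonResult",
    "assign_initial_treatment", "step_cycle", "simulate_patient",
    "simulate_cohort", "run_bootstrap_comparison",
]

NED, BCR, MET, DEATH_PC, DEATH_OC = 0, 1, 2, 3, 4

_OBS, _RT, _HT, _RT_HT = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# random-number plumbing


@dataclass
class DrawSet:
    """Pre-drawn uniforms for a cohort run, one channel per event type.

    Monthly channels have shape ``(n, horizon)``; the two treatment
    decisions are one uniform per patient.  Sharing a DrawSet across arms
    implements common random numbers for every draw whose meaning is
    arm-independent.
    """

    oc: np.ndarray
    pc: np.ndarray
    met: np.ndarray
    bcr: np.ndarray
    redist: np.ndarray
    comp_rt: np.ndarray
    comp_ht: np.ndarray
    adjuvant: np.ndarray
    salvage: np.ndarray

    @classmethod
    def from_rng(cls, rng: np.random.Generator, n: int, horizon: int) -> "DrawSet":
        return cls(
            oc=rng.random((n, horizon)),
            pc=rng.random((n, horizon)),
            met=rng.random((n, horizon)),
            bcr=rng.random((n, horizon)),
            redist=rng.random((n, horizon)),
            comp_rt=rng.random((n, horizon)),
            comp_ht=rng.random((n, horizon)),
            adjuvant=rng.random(n),
            salvage=rng.random(n),
        )

    @property
    def n(self) -> int:
        return self.oc.shape[0]

    @property
    def horizon(self) -> int:
        return self.oc.shape[1]

    def patient(self, i: int) -> "PatientDraws":
        return PatientDraws(
            oc=self.oc[i], pc=self.pc[i], met=self.met[i], bcr=self.bcr[i],
            redist=self.redist[i], comp_rt=self.comp_rt[i],
            comp_ht=self.comp_ht[i],
            adjuvant=float(self.adjuvant[i]), salvage=float(self.salvage[i]),
        )


@dataclass
class PatientDraws:
    """One patient's slice of a :class:`DrawSet`."""

    oc: np.ndarray
    pc: np.ndarray
    met: np.ndarray
    bcr: np.ndarray
    redist: np.ndarray
    comp_rt: np.ndarray
    comp_ht: np.ndarray
    adjuvant: float
    salvage: float


def _modality_from_uniform(u: float, row: np.ndarray) -> int:
    """Map a uniform to a modality index via the row's cumulative sums."""
    cum = np.cumsum(row)
    return int((u >= cum).sum())


# ---------------------------------------------------------------------------
# scalar reference route


@dataclass
class TreatmentState:
    """Mutable treatment bookkeeping for one patient."""

    modality: int = _OBS
    phase: str = "none"  # none | adjuvant | salvage | recurrence_ht
    rt_months_left: int = 0
    ht_months_left: int = 0
    ever_treated: bool = False
    salvage_active: bool = False
    salvage_decided: bool = False
    comp_rt_left: int = 0
    comp_ht_left: int = 0
    started_this_cycle: bool = False

    @property
    def on_treatment(self) -> bool:
        return self.rt_months_left > 0 or self.ht_months_left > 0

    def bucket(self) -> int:
        if self.on_treatment:
            return 1
        return 2 if self.ever_treated else 0


@dataclass
class CycleRecord:
    month: int
    state: int
    on_treatment: bool
    phase: str
    utility: float


@dataclass
class Trajectory:
    """One simulated patient's path and outcome totals."""

    records: list[CycleRecord] = field(default_factory=list)
    ly: float = 0.0
    qaly: float = 0.0
    bcr_month: float = np.inf
    met_month: float = np.inf
    death_month: float = np.inf
    death_cause: str | None = None
    occupancy: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle records as a frame (month, state, treatment, utility)."""
        return pd.DataFrame(
            {
                "month": [r.month for r in self.records],
                "state": [STATE_NAMES[r.state] for r in self.records],
                "on_treatment": [r.on_treatment for r in self.records],
                "phase": [r.phase for r in self.records],
                "utility": [r.utility for r in self.records],
            }
        )

    def add_occupancy(self, state: int, bucket: int, utility: float) -> None:
        key = (STATE_NAMES[state], OCCUPANCY_BUCKETS[bucket])
        cell = self.occupancy.setdefault(key, [0.0, 0.0])
        cell[0] += 1.0
        cell[1] += utility / 12.0


def assign_initial_treatment(
    risk_class: str,
    policy: PolicyTable,
    arm: str,
    u: float,
    params: ModelParams,
) -> TreatmentState:
    """Draw the adjuvant decision at model entry.

    ``arm`` is ``"usual_care"`` or ``"gc_based"``; the guided arm uses the
    gc_low / gc_high adjuvant row according to ``risk_class``.
    Observation defers the salvage decision to first BCR.
    """
    policy_arm = "usual_care" if arm == "usual_care" else (
        "gc_high" if risk_class == "high" else "gc_low"
    )
    row = policy.row_vector("adjuvant", policy_arm)
    modality = _modality_from_uniform(u, row)
    ts = TreatmentState(modality=modality)
    if modality != _OBS:
        ts.phase = "adjuvant"
        ts.ever_treated = True
        if modality in (_RT, _RT_HT):
            ts.rt_months_left = params.durations.radiation_months
        if modality in (_HT, _RT_HT):
            ts.ht_months_left = params.durations.adjuvant_hormone_months
    return ts


def _treatment_utility(ts: TreatmentState, params: ModelParams) -> float:
    u = params.utilities
    if ts.rt_months_left > 0 and ts.ht_months_left > 0:
        return u.rt_ht
    if ts.rt_months_left > 0:
        return u.rt
    if ts.ht_months_left > 0:
        return u.ht
    return 1.0


def _enter_progression(ts: TreatmentState, params: ModelParams) -> None:
    """On entry to BCR or MET for a previously treated patient: stop any
    active course and start the recurrence hormone-therapy course."""
    ts.rt_months_left = 0
    ts.salvage_active = False
    if ts.ever_treated:
        ts.ht_months_left = params.durations.recurrence_hormone_months
        ts.phase = "recurrence_ht"
        ts.started_this_cycle = True
    else:
        ts.ht_months_left = 0
        ts.phase = "none"


def step_cycle(
    state: int,
    ts: TreatmentState,
    params: ModelParams,
    age: float,
    u: dict,
    salvage_row: np.ndarray | None = None,
    include_other_cause: bool = True,
) -> tuple[int, TreatmentState, float]:
    """Advance one monthly cycle; returns (new state, treatment, utility).

    ``u`` maps channel names (``oc, pc, met, bcr, redist, comp_rt,
    comp_ht, salvage``) to this cycle's uniforms.  The cycle's utility is
    the product of the health-state utility, the active-treatment utility,
    and the utilities of any active complications; it applies to the state
    *before* this cycle's transition.
    """
    if state in (DEATH_PC, DEATH_OC):
        raise ValueError("step_cycle called on an absorbing state")
    ts.started_this_cycle = False
    rt_active_at_start = ts.rt_months_left > 0
    ht_active_at_start = ts.ht_months_left > 0
    comp_rt_at_start = ts.comp_rt_left > 0
    comp_ht_at_start = ts.comp_ht_left > 0

    # (a) utility for the cycle
    state_util = (params.utilities.ned, params.utilities.bcr,
                  params.utilities.met)[state]
    utility = state_util * _treatment_utility(ts, params)
    if comp_rt_at_start:
        utility *= params.complications["radiation"].utility
    if comp_ht_at_start:
        utility *= params.complications["hormone"].utility

    # (b) complication onset for active treatments
    comp_rt_started = comp_ht_started = False
    crt = params.complications["radiation"]
    if rt_active_at_start and ts.comp_rt_left == 0 and u["comp_rt"] < crt.onset_monthly:
        ts.comp_rt_left = (
            crt.duration_months if crt.duration_months is not None
            else ts.rt_months_left
        )
        comp_rt_started = True
    cht = params.complications["hormone"]
    if ht_active_at_start and ts.comp_ht_left == 0 and u["comp_ht"] < cht.onset_monthly:
        ts.comp_ht_left = (
            cht.duration_months if cht.duration_months is not None
            else ts.ht_months_left
        )
        comp_ht_started = True

    # (c) competing events in fixed order; at most one fires
    hist = "treated" if ts.ever_treated else "untreated"
    tb = params.transitions[hist]
    new_state = state
    q_oc = params.life_table.monthly(age) if include_other_cause else 0.0
    if u["oc"] < q_oc:
        new_state = DEATH_OC
    elif state == MET and u["pc"] < params.pc_death_from_met:
        new_state = DEATH_PC
    elif state in (NED, BCR) and u["met"] < (
        tb.met_from_ned if state == NED else tb.met_from_bcr
    ):
        new_state = MET
        _enter_progression(ts, params)
    elif state == NED and u["bcr"] < tb.bcr_from_ned:
        new_state = BCR
        if ts.ever_treated:
            _enter_progression(ts, params)
        elif not ts.salvage_decided:
            ts.salvage_decided = True
            if salvage_row is None:
                raise ValueError("salvage_row required for untreated BCR entry")
            modality = _modality_from_uniform(u["salvage"], salvage_row)
            ts.modality = modality
            if modality != _OBS:
                ts.phase = "salvage"
                ts.ever_treated = True
                ts.salvage_active = True
                ts.started_this_cycle = True
                if modality in (_RT, _RT_HT):
                    ts.rt_months_left = params.durations.radiation_months
                if modality in (_HT, _RT_HT):
                    ts.ht_months_left = params.durations.salvage_hormone_months
    elif (
        state == BCR
        and ts.salvage_active
        and (ts.rt_months_left > 0 or ts.ht_months_left > 0)
        and u["redist"] < params.salvage_success_monthly
    ):
        new_state = NED
        ts.salvage_active = False

    # (d) clocks tick at cycle end, but only if active at cycle start
    if rt_active_at_start and not ts.started_this_cycle:
        ts.rt_months_left = max(ts.rt_months_left - 1, 0)
    if ht_active_at_start and not ts.started_this_cycle:
        ts.ht_months_left = max(ts.ht_months_left - 1, 0)
    if comp_rt_at_start and not comp_rt_started:
        ts.comp_rt_left = max(ts.comp_rt_left - 1, 0)
    if comp_ht_at_start and not comp_ht_started:
        ts.comp_ht_left = max(ts.comp_ht_left - 1, 0)
    return new_state, ts, utility


def simulate_patient(
    record: PatientRecord,
    params: ModelParams,
    policy: PolicyTable,
    arm: str = "usual_care",
    draws: PatientDraws | None = None,
    rng: np.random.Generator | None = None,
    threshold: float = DEFAULT_RISK_THRESHOLD,
    include_other_cause: bool = True,
) -> Trajectory:
    """Simulate one patient from prostatectomy to death or the horizon.

    ``params`` should already be individualized if individual-level
    probabilities are wanted (see
    :func:`gcsim.individualization.individualize_params`).  Pass either a
    :class:`PatientDraws` (shared across arms for paired runs) or an
    ``rng`` from which one is drawn.
    """
    if draws is None:
        if rng is None:
            raise ValueError("provide draws or rng")
        draws = DrawSet.from_rng(rng, 1, params.horizon_months).patient(0)
    risk_class = "high" if record.risk5 > threshold else "low"
    ts = assign_initial_treatment(risk_class, policy, arm, draws.adjuvant, params)
    policy_arm = "usual_care" if arm == "usual_care" else (
        "gc_high" if risk_class == "high" else "gc_low"
    )
    salvage_row = policy.row_vector("salvage", policy_arm)

    traj = Trajectory()
    state = NED
    months_alive = 0
    for k in range(params.horizon_months):
        age = record.age_at_rp + k / 12.0
        bucket = ts.bucket()
        u = {
            "oc": draws.oc[k], "pc": draws.pc[k], "met": draws.met[k],
            "bcr": draws.bcr[k], "redist": draws.redist[k],
            "comp_rt": draws.comp_rt[k], "comp_ht": draws.comp_ht[k],
            "salvage": draws.salvage,
        }
        prev_state = state
        state, ts, utility = step_cycle(
            state, ts, params, age, u, salvage_row, include_other_cause
        )
        month = k + 1
        months_alive += 1
        traj.qaly += utility / 12.0
        traj.add_occupancy(prev_state, bucket, utility)
        traj.records.append(
            CycleRecord(month, prev_state, bucket == 1, ts.phase, utility)
        )
        if state != prev_state:
            if state == BCR and not np.isfinite(traj.bcr_month):
                traj.bcr_month = month
            elif state == MET and not np.isfinite(traj.met_month):
                traj.met_month = month
            elif state in (DEATH_PC, DEATH_OC):
                traj.death_month = month
                traj.death_cause = "pc" if state == DEATH_PC else "oc"
                break
    traj.ly = months_alive / 12.0
    return traj


# ---------------------------------------------------------------------------
# vectorized cohort route


@dataclass
class CohortOutcomes:
    """Per-patient outcome arrays from a vectorized cohort run.

    Event months are 1-indexed and ``inf`` when the event never occurs;
    ``death_cause`` is 0 (alive at horizon), 1 (prostate cancer) or 2
    (other causes).  ``occ_months[i, s, b]`` is patient ``i``'s months in
    health state ``s`` and occupancy bucket ``b``; ``occ_qaly`` the QALYs.
    """

    ly: np.ndarray
    qaly: np.ndarray
    bcr_month: np.ndarray
    met_month: np.ndarray
    death_month: np.ndarray
    death_cause: np.ndarray
    occ_months: np.ndarray
    occ_qaly: np.ndarray

    @property
    def n(self) -> int:
        return self.ly.size


def _per_patient_probs(
    params: ModelParams, n: int, scale: np.ndarray | None
) -> dict[str, np.ndarray]:
    out = {}
    for hist in ("untreated", "treated"):
        tb = params.transitions[hist]
        for name, base in (
            ("bcr_from_ned", tb.bcr_from_ned),
            ("met_from_ned", tb.met_from_ned),
            ("met_from_bcr", tb.met_from_bcr),
        ):
            vals = np.full(n, base, dtype=float)
            if scale is not None:
                vals = np.clip(vals * scale, 0.0, 1.0)
            out[f"{hist}.{name}"] = vals
    if scale is not None:
        # extreme up-scaling can push the two NED-exit probabilities past a
        # total of 1; renormalize jointly so the cycle's stay probability
        # stays well defined
        for hist in ("untreated", "treated"):
            tot = out[f"{hist}.bcr_from_ned"] + out[f"{hist}.met_from_ned"]
            f = np.where(tot > 1.0, 1.0 / tot, 1.0)
            out[f"{hist}.bcr_from_ned"] = out[f"{hist}.bcr_from_ned"] * f
            out[f"{hist}.met_from_ned"] = out[f"{hist}.met_from_ned"] * f
    return out


def simulate_cohort(
    ages: np.ndarray,
    risk5: np.ndarray,
    params: ModelParams,
    policy: PolicyTable,
    arm: str,
    draws: DrawSet,
    scale: np.ndarray | None = None,
    threshold: float = DEFAULT_RISK_THRESHOLD,
    include_other_cause: bool = True,
) -> CohortOutcomes:
    """Vectorized simulation of a sampled cohort on a shared DrawSet.

    ``scale`` optionally multiplies every BCR/MET onset probability per
    patient (the risk-individualization ratio), clipped to [0, 1].
    Running two arms on the same DrawSet yields exactly paired outcomes.
    """
    n = draws.n
    horizon = draws.horizon
    ages = np.asarray(ages, dtype=float)
    risk5 = np.asarray(risk5, dtype=float)
    if ages.size != n or risk5.size != n:
        raise ValueError("ages/risk5 length must match the DrawSet")
    if horizon != params.horizon_months:
        raise ValueError("DrawSet horizon differs from params.horizon_months")

    probs = _per_patient_probs(params, n, scale)
    high = risk5 > threshold

    # adjuvant decision
    if arm == "usual_care":
        row = policy.row_vector("adjuvant", "usual_care")
        cum = np.tile(np.cumsum(row), (n, 1))
        salvage_rows = np.tile(
            np.cumsum(policy.row_vector("salvage", "usual_care")), (n, 1)
        )
    elif arm == "gc_based":
        cum = np.where(
            high[:, None],
            np.cumsum(policy.row_vector("adjuvant", "gc_high")),
            np.cumsum(policy.row_vector("adjuvant", "gc_low")),
        )
        salvage_rows = np.where(
            high[:, None],
            np.cumsum(policy.row_vector("salvage", "gc_high")),
            np.cumsum(policy.row_vector("salvage", "gc_low")),
        )
    else:
        raise ValueError(f"unknown arm {arm!r}")
    modality = (draws.adjuvant[:, None] >= cum).sum(axis=1)

    dur = params.durations
    rt_left = np.where(
        (modality == _RT) | (modality == _RT_HT), dur.radiation_months, 0
    ).astype(np.int32)
    ht_left = np.where(
        (modality == _HT) | (modality == _RT_HT), dur.adjuvant_hormone_months, 0
    ).astype(np.int32)
    ever_treated = modality != _OBS
    salvage_active = np.zeros(n, dtype=bool)
    salvage_decided = np.zeros(n, dtype=bool)
    comp_rt_left = np.zeros(n, dtype=np.int32)
    comp_ht_left = np.zeros(n, dtype=np.int32)

    state = np.zeros(n, dtype=np.int8)
    months_alive = np.zeros(n, dtype=np.int32)
    qaly = np.zeros(n)
    bcr_month = np.full(n, np.inf)
    met_month = np.full(n, np.inf)
    death_month = np.full(n, np.inf)
    death_cause = np.zeros(n, dtype=np.int8)
    occ_months = np.zeros((n, 3, 3))
    occ_qaly = np.zeros((n, 3, 3))
    occ_months_flat = occ_months.reshape(n, 9)
    occ_qaly_flat = occ_qaly.reshape(n, 9)

    u_state = np.array(
        [params.utilities.ned, params.utilities.bcr, params.utilities.met,
         0.0, 0.0]
    )
    crt = params.complications["radiation"]
    cht = params.complications["hormone"]
    idx_all = np.arange(n)

    for k in range(horizon):
        alive = state < DEATH_PC
        if not alive.any():
            break
        rt_at_start = rt_left > 0
        ht_at_start = ht_left > 0
        comp_rt_at_start = comp_rt_left > 0
        comp_ht_at_start = comp_ht_left > 0
        started = np.zeros(n, dtype=bool)
        comp_rt_started = np.zeros(n, dtype=bool)
        comp_ht_started = np.zeros(n, dtype=bool)

        # (a) utility and accrual
        treat_util = np.where(
            rt_at_start & ht_at_start, params.utilities.rt_ht,
            np.where(rt_at_start, params.utilities.rt,
                     np.where(ht_at_start, params.utilities.ht, 1.0)),
        )
        util = u_state[state] * treat_util
        util = np.where(comp_rt_at_start, util * crt.utility, util)
        util = np.where(comp_ht_at_start, util * cht.utility, util)
        months_alive += alive
        qaly += np.where(alive, util / 12.0, 0.0)
        bucket = np.where(
            rt_at_start | ht_at_start, 1, np.where(ever_treated, 2, 0)
        )
        cell = state.astype(np.int32) * 3 + bucket
        live_idx = idx_all[alive]
        np.add.at(occ_months_flat, (live_idx, cell[alive]), 1.0)
        np.add.at(occ_qaly_flat, (live_idx, cell[alive]), util[alive] / 12.0)

        # (b) complication onset
        onset_rt = (
            alive & rt_at_start & (comp_rt_left == 0)
            & (draws.comp_rt[:, k] < crt.onset_monthly)
        )
        comp_rt_left[onset_rt] = (
            crt.duration_months if crt.duration_months is not None
            else rt_left[onset_rt]
        )
        comp_rt_started |= onset_rt
        onset_ht = (
            alive & ht_at_start & (comp_ht_left == 0)
            & (draws.comp_ht[:, k] < cht.onset_monthly)
        )
        comp_ht_left[onset_ht] = (
            cht.duration_months if cht.duration_months is not None
            else ht_left[onset_ht]
        )
        comp_ht_started |= onset_ht

        # (c) events in fixed order, at most one per patient
        month = k + 1
        if include_other_cause:
            q_oc = params.life_table.monthly_vector(ages + k / 12.0)
        else:
            q_oc = np.zeros(n)
        d_oc = alive & (draws.oc[:, k] < q_oc)
        state[d_oc] = DEATH_OC
        death_month[d_oc] = month
        death_cause[d_oc] = 2
        moved = d_oc

        rem = alive & ~moved
        d_pc = rem & (state == MET) & (draws.pc[:, k] < params.pc_death_from_met)
        state[d_pc] = DEATH_PC
        death_month[d_pc] = month
        death_cause[d_pc] = 1
        moved |= d_pc

        rem = alive & ~moved
        p_met = np.where(
            state == NED,
            np.where(ever_treated, probs["treated.met_from_ned"],
                     probs["untreated.met_from_ned"]),
            np.where(ever_treated, probs["treated.met_from_bcr"],
                     probs["untreated.met_from_bcr"]),
        )
        to_met = rem & ((state == NED) | (state == BCR)) & (draws.met[:, k] < p_met)
        if to_met.any():
            met_month[to_met] = month
            state[to_met] = MET
            rt_left[to_met] = 0
            salvage_active[to_met] = False
            start_rec = to_met & ever_treated
            ht_left[start_rec] = dur.recurrence_hormone_months
            started |= start_rec
            ht_left[to_met & ~ever_treated] = 0
        moved |= to_met

        rem = alive & ~moved
        p_bcr = np.where(ever_treated, probs["treated.bcr_from_ned"],
                         probs["untreated.bcr_from_ned"])
        to_bcr = rem & (state == NED) & (draws.bcr[:, k] < p_bcr)
        if to_bcr.any():
            state[to_bcr] = BCR
            first = to_bcr & ~np.isfinite(bcr_month)
            bcr_month[first] = month
            rec = to_bcr & ever_treated
            rt_left[rec] = 0
            salvage_active[rec] = False
            ht_left[rec] = dur.recurrence_hormone_months
            started |= rec
            # salvage decision for previously untreated patients
            dec = to_bcr & ~ever_treated & ~salvage_decided
            if dec.any():
                salvage_decided |= dec
                s_mod = (draws.salvage[:, None] >= salvage_rows).sum(axis=1)
                treat = dec & (s_mod != _OBS)
                ever_treated |= treat
                salvage_active |= treat
                started |= treat
                rt_sal = treat & ((s_mod == _RT) | (s_mod == _RT_HT))
                rt_left[rt_sal] = dur.radiation_months
                ht_sal = treat & ((s_mod == _HT) | (s_mod == _RT_HT))
                ht_left[ht_sal] = dur.salvage_hormone_months
        moved |= to_bcr

        rem = alive & ~moved
        redist = (
            rem & (state == BCR) & salvage_active
            & ((rt_left > 0) | (ht_left > 0))
            & (draws.redist[:, k] < params.salvage_success_monthly)
        )
        state[redist] = NED
        salvage_active[redist] = False

        # (d) clocks tick at cycle end if active at cycle start
        tick = rt_at_start & ~started
        rt_left[tick] = np.maximum(rt_left[tick] - 1, 0)
        tick = ht_at_start & ~started
        ht_left[tick] = np.maximum(ht_left[tick] - 1, 0)
        tick = comp_rt_at_start & ~comp_rt_started
        comp_rt_left[tick] = np.maximum(comp_rt_left[tick] - 1, 0)
        tick = comp_ht_at_start & ~comp_ht_started
        comp_ht_left[tick] = np.maximum(comp_ht_left[tick] - 1, 0)

    return CohortOutcomes(
        ly=months_alive / 12.0,
        qaly=qaly,
        bcr_month=bcr_month,
        met_month=met_month,
        death_month=death_month,
        death_cause=death_cause,
        occ_months=occ_months,
        occ_qaly=occ_qaly,
    )


# ---------------------------------------------------------------------------
# paired bootstrap comparison


@dataclass(frozen=True)
class Arm:
    """One policy/probability configuration of the comparison."""

    name: str
    policy_arm: str = "usual_care"  # usual_care | gc_based
    individualized: bool = False


@dataclass
class ComparisonResult:
    """Paired outcomes for two arms simulated with common random numbers."""

    arm_a: Arm
    arm_b: Arm
    outcomes_a: CohortOutcomes
    outcomes_b: CohortOutcomes
    n_samples: int
    seed: int
    r_model: float | None

    def mean_ci(self, which: str, arm: str) -> tuple[float, float, float]:
        x = getattr(self.outcomes_a if arm == "a" else self.outcomes_b, which)
        m = float(x.mean())
        half = 1.96 * float(x.std(ddof=1)) / np.sqrt(x.size)
        return m, m - half, m + half

    def deltas(self, which: str) -> np.ndarray:
        return getattr(self.outcomes_b, which) - getattr(self.outcomes_a, which)

    def summary(self) -> pd.DataFrame:
        """Tabulate LY/QALY means, event probabilities with 95% CIs, and
        paired test p-values, one row per outcome."""
        rows = []
        for which in ("ly", "qaly"):
            ma = self.mean_ci(which, "a")
            mb = self.mean_ci(which, "b")
            d = self.deltas(which)
            tstat, p = _stats.paired_ttest(d)
            rows.append({
                "outcome": which.upper(),
                "arm_a": ma[0], "arm_a_lo": ma[1], "arm_a_hi": ma[2],
                "arm_b": mb[0], "arm_b_lo": mb[1], "arm_b_hi": mb[2],
                "delta": float(d.mean()), "p_value": p, "test": "paired_t",
            })
        for label, event, t in (
            ("5y_bcr_free_survival", "bcr_free_survival", 60),
            ("10y_bcr_free_survival", "bcr_free_survival", 120),
            ("5y_met_or_death", "met_or_death", 60),
            ("10y_met_or_death", "met_or_death", 120),
        ):
            ia = _stats.event_indicator(self.outcomes_a, event, t)
            ib = _stats.event_indicator(self.outcomes_b, event, t)
            pa, loa, hia = _stats.event_probability_from_indicator(ia)
            pb, lob, hib = _stats.event_probability_from_indicator(ib)
            stat, p, _method = _stats.mcnemar_test(ia, ib)
            rows.append({
                "outcome": label,
                "arm_a": pa, "arm_a_lo": loa, "arm_a_hi": hia,
                "arm_b": pb, "arm_b_lo": lob, "arm_b_hi": hib,
                "delta": pb - pa, "p_value": p, "test": "mcnemar",
            })
        df = pd.DataFrame(rows)
        df.insert(1, "arm_a_name", self.arm_a.name)
        df.insert(2, "arm_b_name", self.arm_b.name)
        return df

    def occupancy_summary(self) -> pd.DataFrame:
        frames = []
        for arm, out in (
            (self.arm_a.name, self.outcomes_a),
            (self.arm_b.name, self.outcomes_b),
        ):
            df = _stats.state_occupancy_summary(out)
            df.insert(0, "arm", arm)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_bootstrap_comparison(
    cohort: pd.DataFrame,
    params: ModelParams,
    policy: PolicyTable,
    arm_a: Arm,
    arm_b: Arm,
    n_samples: int = 10_000,
    seed: int = 0,
    r_model: float | None = None,
    threshold: float = DEFAULT_RISK_THRESHOLD,
    include_other_cause: bool = True,
) -> ComparisonResult:
    """Paired bootstrap comparison of two arms over a cohort.

    ``n_samples`` patients are drawn with replacement once; each sampled
    patient is then simulated under both arms on the same
    :class:`DrawSet`, so every draw whose meaning is shared between arms
    (other-cause death, event and complication uniforms, decision
    uniforms) is identical — identical arms give exactly zero deltas.
    ``r_model`` (the model-predicted population 5-year metastasis risk)
    is required when either arm uses individualized probabilities.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if (arm_a.individualized or arm_b.individualized) and not r_model:
        raise ValueError("r_model is required for individualized arms")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cohort), size=n_samples)
    ages = cohort["age_at_rp"].to_numpy(float)[idx]
    risk5 = cohort["risk5"].to_numpy(float)[idx]
    draws = DrawSet.from_rng(rng, n_samples, params.horizon_months)

    def run(arm: Arm) -> CohortOutcomes:
        scale = risk5 / r_model if arm.individualized else None
        return simulate_cohort(
            ages, risk5, params, policy, arm.policy_arm, draws,
            scale=scale, threshold=threshold,
            include_other_cause=include_other_cause,
        )

    return ComparisonResult(
        arm_a=arm_a, arm_b=arm_b,
        outcomes_a=run(arm_a), outcomes_b=run(arm_b),
        n_samples=n_samples, seed=seed, r_model=r_model,
    )
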