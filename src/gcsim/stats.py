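"""Outcome aggregation and the statistical comparisons.

Event probabilities carry Wald (normal-approximation) binomial 95%
intervals; continuous outcomes are compared with paired t-tests and
binary outcomes with McNemar's test on the discordant pairs, matching a
paired common-random-numbers simulation design.  Kaplan-Meier estimates
are provided for validating simulated event probabilities against
product-limit estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "STATE_NAMES",
    "OCCUPANCY_BUCKETS",
    "PairedOutcome",
    "wald_ci",
    "event_indicator",
    "event_probability",
    "event_probability_from_indicator",
    "km_estimate",
    "km_survival_at",
    "paired_ttest",
    "mcnemar_test",
    "mcnemar_from_counts",
    "state_occupancy_summary",
]

#: health-state labels, in the engine's integer coding order
STATE_NAMES = ("NED", "BCR", "MET", "DEATH_PC", "DEATH_OC")
#: occupancy decomposition of time alive
OCCUPANCY_BUCKETS = ("untreated", "on_treatment", "post_treatment")

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class PairedOutcome:
    """Per-sample paired values for one outcome under two arms."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        if len(self.a) != len(self.b):
            raise ValueError("paired outcome arrays differ in length")

    @property
    def deltas(self) -> np.ndarray:
        return np.asarray(self.b, dtype=float) - np.asarray(self.a, dtype=float)


def wald_ci(p_hat: float, n: int, z: float = _Z95) -> tuple[float, float]:
    """Normal-approximation binomial CI, ``p ± z sqrt(p(1-p)/n)``.

    Degenerate at ``p_hat`` of 0 or 1 (zero width), like the printed
    intervals it is meant to reproduce.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return float(max(p_hat - half, 0.0)), float(min(p_hat + half, 1.0))


def event_indicator(
    outcomes, event: str, t: float, pc_death_only: bool = False
) -> np.ndarray:
    """Binary per-patient outcome indicators at month ``t``.

    ``event`` is one of:

    - ``"bcr"`` — biochemical recurrence by ``t``;
    - ``"met"`` — metastasis by ``t``;
    - ``"met_or_death"`` — metastasis or death by ``t`` (death from any
      cause by default; ``pc_death_only`` restricts to prostate-cancer
      death);
    - ``"bcr_free_survival"`` — alive *and* recurrence-free at ``t``.
    """
    if event == "bcr":
        return outcomes.bcr_month <= t
    if event == "met":
        return outcomes.met_month <= t
    if event == "met_or_death":
        death = outcomes.death_month <= t
        if pc_death_only:
            death &= outcomes.death_cause == 1
        return (outcomes.met_month <= t) | death
    if event == "bcr_free_survival":
        return (outcomes.bcr_month > t) & (outcomes.death_month > t)
    raise ValueError(f"unknown event {event!r}")


def event_probability_from_indicator(
    indicator: np.ndarray,
) -> tuple[float, float, float]:
    indicator = np.asarray(indicator)
    if indicator.size == 0:
        raise ValueError("no observations")
    p = float(indicator.mean())
    lo, hi = wald_ci(p, indicator.size)
    return p, lo, hi


def event_probability(
    outcomes, event: str, t: float, pc_death_only: bool = False
) -> tuple[float, float, float]:
    """Proportion with the event by month ``t``, with Wald 95% CI."""
    return event_probability_from_indicator(
        event_indicator(outcomes, event, t, pc_death_only)
    )


def km_estimate(durations, event_observed) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    ``durations`` are times to event or censoring; ``event_observed`` is
    1 for events, 0 for censored.  Returns a step function as a frame
    with columns ``time`` and ``survival``.
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(event_observed)
    if durations.size == 0:
        raise ValueError("no observations")
    if np.any(durations < 0):
        raise ValueError("durations must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate a Kaplan-Meier step function at time ``t``."""
    mask = km["time"].to_numpy() <= t
    if not mask.any():
        return 1.0
    return float(km.loc[mask, "survival"].iloc[-1])


def paired_ttest(deltas) -> tuple[float, float]:
    """Two-sided one-sample t-test of paired differences against zero.

    All-zero differences (the common-random-numbers identity case) return
    ``(0.0, 1.0)`` by convention.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two paired differences")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def mcnemar_from_counts(
    b: int, c: int, exact_threshold: int = 25, correction: bool = False
) -> tuple[float, float, str]:
    """McNemar's test from discordant counts.

    ``b`` = pairs positive under arm A only, ``c`` = under arm B only.
    Uses the exact binomial test when ``b + c < exact_threshold``,
    otherwise the chi-square statistic ``(b - c)^2 / (b + c)`` (without
    continuity correction unless requested).  ``b + c == 0`` gives
    ``p = 1`` by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return 0.0, 1.0, "degenerate"
    table = np.array([[0, b], [c, 0]])
    if b + c < exact_threshold:
        res = _sm_mcnemar(table, exact=True)
        return float(min(b, c)), float(min(res.pvalue, 1.0)), "exact"
    res = _sm_mcnemar(table, exact=False, correction=correction)
    return float(res.statistic), float(res.pvalue), "chi2"


def mcnemar_test(
    a, b, exact_threshold: int = 25, correction: bool = False
) -> tuple[float, float, str]:
    """McNemar's test for paired binary outcomes (arrays of 0/1)."""
    a = np.asarray(a).astype(bool)
    bb = np.asarray(b).astype(bool)
    if a.size != bb.size:
        raise ValueError("paired outcome arrays differ in length")
    n_b = int(np.sum(a & ~bb))
    n_c = int(np.sum(~a & bb))
    return mcnemar_from_counts(n_b, n_c, exact_threshold, correction)


def state_occupancy_summary(outcomes) -> pd.DataFrame:
    """Mean life-years and QALYs spent in each (state, treatment) cell.

    The cell sums reconcile with the cohort's mean total LY and QALY to
    numerical precision (time alive is fully partitioned).
    """
    if outcomes.n == 0:
        raise ValueError("no simulated patients")
    mean_months = outcomes.occ_months.mean(axis=0)
    mean_qaly = outcomes.occ_qaly.mean(axis=0)
    rows = []
    for s, sname in enumerate(STATE_NAMES[:3]):
        for b, bname in enumerate(OCCUPANCY_BUCKETS):
            rows.append(
                {
                    "state": sname,
                    "treatment": bname,
                    "ly": mean_months[s, b] / 12.0,
                    "qaly": mean_qaly[s, b],
                }
            )
    df = pd.DataFrame(rows)
    total = pd.DataFrame(
        [{
            "state": "TOTAL", "treatment": "",
            "ly": df["ly"].sum(), "qaly": df["qaly"].sum(),
        }]
    )
    return pd.concat([df, total], ignore_index=True)
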