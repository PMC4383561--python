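"""One-way, probabilistic, and treatment-aggressiveness sensitivity
analyses.

All scenario reruns reuse the base run's master seed, so the bootstrap
sample and every event uniform are common random numbers across
scenarios: a perturbation that does not change any parameter reproduces
the base expected QALYs exactly, and tornado deltas isolate the
parameter's effect from Monte-Carlo noise.

The population-risk calibration ``R_model`` is held at its base-case
value across scenarios; perturbations measure outcome sensitivity at a
fixed individualization, not a re-calibrated model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import Arm, DrawSet, simulate_cohort
from .parameters import (
    MODALITIES,
    ModelParams,
    ParameterError,
    PolicyTable,
    get_param,
    set_param,
)

__all__ = [
    "DEFAULT_SENSITIVITY_PATHS",
    "expected_qalys",
    "one_way_sensitivity",
    "beta_from_mean_rel_range",
    "sample_params",
    "probabilistic_sensitivity",
    "vary_observation_share",
    "aggressiveness_analysis",
]

#: parameter paths swept by default: every transition/event probability
#: and every utility of the model
DEFAULT_SENSITIVITY_PATHS = (
    "transitions.untreated.bcr_from_ned",
    "transitions.untreated.met_from_ned",
    "transitions.untreated.met_from_bcr",
    "transitions.treated.bcr_from_ned",
    "transitions.treated.met_from_ned",
    "transitions.treated.met_from_bcr",
    "pc_death_from_met",
    "salvage_success_monthly",
    "complications.radiation.onset_monthly",
    "complications.hormone.onset_monthly",
    "utilities.ned",
    "utilities.bcr",
    "utilities.met",
    "utilities.rt",
    "utilities.ht",
    "utilities.rt_ht",
    "complications.radiation.utility",
    "complications.hormone.utility",
)

_UTILITY_HINTS = ("utilities.", ".utility")


def _is_utility_path(path: str) -> bool:
    return any(h in path for h in _UTILITY_HINTS)


def _perturbed(params: ModelParams, path: str, factor: float) -> ModelParams:
    value = get_param(params, path) * factor
    value = min(max(value, 0.0), 1.0)
    if _is_utility_path(path):
        value = max(value, 1e-9)  # utilities stay strictly positive
    return set_param(params, path, value)


def expected_qalys(
    cohort: pd.DataFrame,
    params: ModelParams,
    policy: PolicyTable,
    arm: Arm,
    n_samples: int,
    seed: int,
    r_model: float | None = None,
    include_other_cause: bool = True,
) -> tuple[float, float]:
    """Mean (QALY, LY) for one arm, with the bootstrap sample and all
    event uniforms derived deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cohort), size=n_samples)
    ages = cohort["age_at_rp"].to_numpy(float)[idx]
    risk5 = cohort["risk5"].to_numpy(float)[idx]
    draws = DrawSet.from_rng(rng, n_samples, params.horizon_months)
    scale = None
    if arm.individualized:
        if not r_model:
            raise ValueError("r_model required for an individualized arm")
        scale = risk5 / r_model
    out = simulate_cohort(
        ages, risk5, params, policy, arm.policy_arm, draws,
        scale=scale, include_other_cause=include_other_cause,
    )
    return float(out.qaly.mean()), float(out.ly.mean())


def one_way_sensitivity(
    params: ModelParams,
    policy: PolicyTable,
    cohort: pd.DataFrame,
    paths=DEFAULT_SENSITIVITY_PATHS,
    rel: float = 0.10,
    n_samples: int = 5_000,
    seed: int = 0,
    arm: Arm | None = None,
    r_model: float | None = None,
    include_other_cause: bool = True,
) -> pd.DataFrame:
    """One-way ±``rel`` sweep of each parameter; tornado-ordered output.

    Every scenario is a paired rerun on the base seed, so ``delta_qaly``
    is exactly zero for perturbations with no causal path to outcomes.
    Returns one row per (parameter, direction) sorted by the parameter's
    largest absolute QALY change.
    """
    if arm is None:
        arm = Arm("gc_based_individualized", "gc_based", True)
    base_qaly, _ = expected_qalys(
        cohort, params, policy, arm, n_samples, seed, r_model,
        include_other_cause,
    )
    rows = []
    for path in paths:
        base_value = get_param(params, path)
        for direction, factor in (("low", 1.0 - rel), ("high", 1.0 + rel)):
            scenario = _perturbed(params, path, factor)
            q, _ = expected_qalys(
                cohort, scenario, policy, arm, n_samples, seed, r_model,
                include_other_cause,
            )
            rows.append(
                {
                    "parameter": path,
                    "direction": direction,
                    "base_value": base_value,
                    "scenario_value": get_param(scenario, path),
                    "qaly": q,
                    "delta_qaly": q - base_qaly,
                }
            )
    df = pd.DataFrame(rows)
    order = (
        df.groupby("parameter")["delta_qaly"]
        .apply(lambda s: s.abs().max())
        .sort_values(ascending=False)
    )
    df["rank"] = df["parameter"].map(
        {p: i for i, p in enumerate(order.index)}
    )
    df = df.sort_values(["rank", "direction"]).drop(columns="rank")
    df.attrs["base_qaly"] = base_qaly
    return df.reset_index(drop=True)


def beta_from_mean_rel_range(
    mean: float, rel: float = 0.10
) -> tuple[float, float] | None:
    """Beta parameters whose mean is ``mean`` and whose ±``rel`` relative
    range corresponds to a 95% interval (±1.96 sd).

    Returns ``None`` for a degenerate (zero-variance) specification.
    Raises :class:`ParameterError` when no beta distribution has the
    requested moments.
    """
    if rel == 0.0 or mean in (0.0, 1.0):
        return None
    if not (0.0 < mean < 1.0):
        raise ParameterError(f"mean {mean} outside (0, 1)")
    sd = rel * mean / 1.959963984540054
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"moment matching infeasible: variance {var:.3g} >= "
            f"mean*(1-mean) = {mean * (1 - mean):.3g}"
        )
    a = mean * (mean * (1.0 - mean) / var - 1.0)
    return a, a * (1.0 - mean) / mean


def sample_params(
    params: ModelParams,
    rng: np.random.Generator,
    paths=DEFAULT_SENSITIVITY_PATHS,
    rel: float = 0.10,
) -> ModelParams:
    """Draw one parameter set with each path sampled from its beta
    distribution (moments matched to the base value and its ±``rel``
    range as a 95% interval)."""
    out = params
    for path in paths:
        base = get_param(params, path)
        ab = beta_from_mean_rel_range(base, rel)
        value = base if ab is None else float(rng.beta(*ab))
        if _is_utility_path(path):
            value = min(max(value, 1e-9), 1.0)
        out = set_param(out, path, value)
    return out


def probabilistic_sensitivity(
    params: ModelParams,
    policy: PolicyTable,
    cohort: pd.DataFrame,
    paths=DEFAULT_SENSITIVITY_PATHS,
    rel: float = 0.10,
    n_draws: int = 200,
    n_samples: int = 2_000,
    seed: int = 0,
    r_model: float | None = None,
    include_other_cause: bool = True,
) -> dict:
    """Probabilistic sensitivity analysis of the guided-care comparison.

    Each draw samples all swept probabilities and utilities from beta
    distributions, reruns the paired usual-care vs guided-care comparison
    at a reduced inner sample size, and records the QALY difference.
    Returns the distribution summary and the fraction of draws favoring
    guided care.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    usual = Arm("usual_care_individualized", "usual_care", True)
    guided = Arm("gc_based_individualized", "gc_based", True)
    inner_seed = int(rng.integers(0, 2**31 - 1))
    deltas = np.empty(n_draws)
    for i in range(n_draws):
        drawn = sample_params(params, rng, paths, rel)
        q_usual, _ = expected_qalys(
            cohort, drawn, policy, usual, n_samples, inner_seed, r_model,
            include_other_cause,
        )
        q_gc, _ = expected_qalys(
            cohort, drawn, policy, guided, n_samples, inner_seed, r_model,
            include_other_cause,
        )
        deltas[i] = q_gc - q_usual
    return {
        "n_draws": n_draws,
        "delta_qaly_mean": float(deltas.mean()),
        "delta_qaly_sd": float(deltas.std(ddof=1)) if n_draws > 1 else 0.0,
        "delta_qaly_q025": float(np.quantile(deltas, 0.025)),
        "delta_qaly_q975": float(np.quantile(deltas, 0.975)),
        "prob_gc_favored": float(np.mean(deltas > 0)),
        "deltas": deltas,
    }


def vary_observation_share(row: dict, shift: float) -> dict:
    """Shift a decision row's observation share by ``shift`` (absolute).

    The new observation probability is clamped to [0, 1]; the remaining
    mass is spread over the active treatments preserving their relative
    ratios.  Raises when all treatment probabilities are zero but mass
    must be assigned to them.
    """
    missing = set(MODALITIES) - set(row)
    if missing:
        raise ParameterError(f"policy row missing modalities {sorted(missing)}")
    obs = min(max(row["observation"] + shift, 0.0), 1.0)
    rest = 1.0 - obs
    treat_total = sum(row[m] for m in MODALITIES if m != "observation")
    out = {"observation": obs}
    if treat_total == 0.0:
        if rest > 1e-12:
            raise ParameterError(
                "cannot redistribute mass: all treatment probabilities are zero"
            )
        for m in MODALITIES[1:]:
            out[m] = 0.0
    else:
        for m in MODALITIES[1:]:
            out[m] = row[m] * rest / treat_total
    return out


def aggressiveness_analysis(
    params: ModelParams,
    policy: PolicyTable,
    cohort: pd.DataFrame,
    shifts=(-0.20, 0.0, 0.20),
    contexts=("adjuvant", "salvage"),
    arms=("gc_low", "gc_high"),
    n_samples: int = 5_000,
    seed: int = 0,
    r_model: float | None = None,
    include_other_cause: bool = True,
) -> pd.DataFrame:
    """Guided-care QALY gain as treatment aggressiveness varies.

    Each scenario shifts the observation share of the guided-care
    decision rows by the given absolute amount (negative = more
    aggressive treatment) and reruns the usual-care vs guided-care
    comparison with common random numbers.
    """
    usual = Arm("usual_care_individualized", "usual_care", True)
    guided = Arm("gc_based_individualized", "gc_based", True)
    q_usual, _ = expected_qalys(
        cohort, params, policy, usual, n_samples, seed, r_model,
        include_other_cause,
    )
    rows = []
    for shift in shifts:
        scenario = policy
        for context in contexts:
            for arm in arms:
                scenario = scenario.replace_row(
                    context, arm,
                    vary_observation_share(scenario.row(context, arm), shift),
                )
        q_gc, _ = expected_qalys(
            cohort, params, scenario, guided, n_samples, seed, r_model,
            include_other_cause,
        )
        rows.append(
            {
                "observation_shift": shift,
                "qaly_usual": q_usual,
                "qaly_gc": q_gc,
                "delta_qaly": q_gc - q_usual,
            }
        )
    return pd.DataFrame(rows)
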