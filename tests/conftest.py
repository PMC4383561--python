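import numpy as np
import pandas as pd
import pytest

from gcsim.parameters import (
    Complication,
    Durations,
    LifeTable,
    ModelParams,
    TransitionBlock,
    Utilities,
    default_params,
    default_policy,
)
from gcsim.cohort_io import COHORT_COLUMNS


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def policy():
    return default_policy()


def make_flat_params(
    bcr=0.0,
    met_ned=0.0,
    met_bcr=0.0,
    pc_death=0.0,
    salvage_success=0.0,
    comp_rt=0.0,
    comp_ht=0.0,
    oc_monthly=0.0,
    utilities=None,
    horizon=120,
    durations=None,
) -> ModelParams:
    """Parameter sets with identical treated/untreated blocks and a flat
    (age-independent) other-cause mortality, for closed-form oracles."""
    annual = 1.0 - (1.0 - oc_monthly) ** 12
    lt = LifeTable(np.arange(30, 111), np.full(81, annual))
    u = utilities or {}
    block = TransitionBlock(
        bcr_from_ned=bcr, met_from_ned=met_ned, met_from_bcr=met_bcr
    )
    return ModelParams(
        transitions={
            "untreated": TransitionBlock(**vars(block)),
            "treated": TransitionBlock(**vars(block)),
        },
        pc_death_from_met=pc_death,
        salvage_success_monthly=salvage_success,
        complications={
            "radiation": Complication(onset_monthly=comp_rt, utility=u.get("comp_rt", 1.0)),
            "hormone": Complication(onset_monthly=comp_ht, utility=u.get("comp_ht", 1.0)),
        },
        utilities=Utilities(
            ned=u.get("ned", 1.0), bcr=u.get("bcr", 1.0), met=u.get("met", 1.0),
            rt=u.get("rt", 1.0), ht=u.get("ht", 1.0), rt_ht=u.get("rt_ht", 1.0),
        ),
        durations=durations or Durations(),
        life_table=lt,
        horizon_months=horizon,
    ).validate()


def observation_only_policy():
    row = {"observation": 1.0, "rt": 0.0, "ht": 0.0, "rt_ht": 0.0}
    from gcsim.parameters import POLICY_ARMS, POLICY_CONTEXTS, PolicyTable

    return PolicyTable(
        {(c, a): dict(row) for c in POLICY_CONTEXTS for a in POLICY_ARMS}
    )


def make_cohort(ages, risks, is_control=False, cohort="synthetic"):
    ages = np.atleast_1d(np.asarray(ages, float))
    risks = np.atleast_1d(np.asarray(risks, float))
    n = ages.size
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "cohort": cohort,
            "age_at_rp": ages,
            "risk5": risks,
            "risk5_lo": np.clip(risks * 0.6, 0, 1),
            "risk5_hi": np.clip(risks * 1.4, 0, 1),
            "is_control": np.broadcast_to(np.asarray(is_control, bool), n).copy(),
            "weight": 1,
        },
        columns=COHORT_COLUMNS,
    )


@pytest.fixture(scope="session")
def small_cohort():
    rng = np.random.default_rng(11)
    return make_cohort(rng.uniform(50, 78, 60), rng.uniform(0.01, 0.3, 60))
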