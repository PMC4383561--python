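import numpy as np
import pytest

from gcsim.cohort_io import PatientRecord
from gcsim.engine import (
    BCR,
    DEATH_OC,
    MET,
    NED,
    Arm,
    DrawSet,
    TreatmentState,
    assign_initial_treatment,
    run_bootstrap_comparison,
    simulate_cohort,
    simulate_patient,
    step_cycle,
)
from gcsim.parameters import Durations, PolicyTable, POLICY_ARMS, POLICY_CONTEXTS

from .conftest import make_cohort, make_flat_params, observation_only_policy


def degenerate_policy(modality: str) -> PolicyTable:
    row = {m: 0.0 for m in ("observation", "rt", "ht", "rt_ht")}
    row[modality] = 1.0
    return PolicyTable(
        {(c, a): dict(row) for c in POLICY_CONTEXTS for a in POLICY_ARMS}
    )


def record(age=65.0, risk=0.08):
    return PatientRecord("p0", age, risk, risk * 0.6, min(risk * 1.4, 1.0))


class TestStepCycle:
    def test_quiet_cycle_stays_ned_with_full_utility(self):
        params = make_flat_params()
        u = {k: 0.99 for k in
             ("oc", "pc", "met", "bcr", "redist", "comp_rt", "comp_ht", "salvage")}
        state, ts, util = step_cycle(NED, TreatmentState(), params, 65.0, u)
        assert state == NED
        assert util == 1.0

    def test_certain_other_cause_death(self):
        params = make_flat_params(oc_monthly=1.0)
        u = {k: 0.5 for k in
             ("oc", "pc", "met", "bcr", "redist", "comp_rt", "comp_ht", "salvage")}
        state, _, _ = step_cycle(NED, TreatmentState(), params, 65.0, u)
        assert state == DEATH_OC

    def test_multiplicative_utility_stacking(self):
        # health state 0.9 x treatment 0.8 x complication 0.9 = 0.648
        params = make_flat_params(
            utilities={"ned": 0.9, "rt": 0.8, "comp_rt": 0.9}
        )
        ts = TreatmentState(rt_months_left=2, ever_treated=True, comp_rt_left=3)
        u = {k: 0.99 for k in
             ("oc", "pc", "met", "bcr", "redist", "comp_rt", "comp_ht", "salvage")}
        _, _, util = step_cycle(NED, ts, params, 65.0, u)
        assert util == pytest.approx(0.9 * 0.8 * 0.9, abs=1e-12)

    def test_absorbing_state_rejected(self):
        params = make_flat_params()
        with pytest.raises(ValueError):
            step_cycle(DEATH_OC, TreatmentState(), params, 65.0, {})


class TestAdjuvantAssignment:
    def test_degenerate_rows(self, params):
        obs = assign_initial_treatment(
            "low", degenerate_policy("observation"), "usual_care", 0.5, params
        )
        assert not obs.ever_treated and not obs.on_treatment
        rt = assign_initial_treatment(
            "low", degenerate_policy("rt"), "usual_care", 0.5, params
        )
        assert rt.ever_treated and rt.rt_months_left == params.durations.radiation_months

    def test_multinomial_frequencies(self, params):
        row = {"observation": 0.5, "rt": 0.3, "ht": 0.1, "rt_ht": 0.1}
        policy = PolicyTable(
            {(c, a): dict(row) for c in POLICY_CONTEXTS for a in POLICY_ARMS}
        )
        n = 20_000
        u = np.random.default_rng(5).random(n)
        counts = np.zeros(4)
        for ui in u:
            ts = assign_initial_treatment("low", policy, "usual_care", ui, params)
            counts[ts.modality] += 1
        freqs = counts / n
        targets = np.array([0.5, 0.3, 0.1, 0.1])
        se = np.sqrt(targets * (1 - targets) / n)
        assert np.all(np.abs(freqs - targets) < 3 * se + 1e-9)

    def test_gc_arm_uses_risk_class_rows(self, params, policy):
        # gc_high row has observation 0.25, gc_low has 0.85: a uniform of
        # 0.5 treats a high-risk patient but observes a low-risk one
        high = assign_initial_treatment("high", policy, "gc_based", 0.5, params)
        low = assign_initial_treatment("low", policy, "gc_based", 0.5, params)
        assert high.ever_treated and not low.ever_treated


class TestSimulatePatient:
    def test_zero_event_patient_full_horizon(self):
        params = make_flat_params()
        rng = np.random.default_rng(0)
        traj = simulate_patient(
            record(), params, observation_only_policy(), rng=rng
        )
        assert traj.ly == pytest.approx(10.0, abs=1e-12)
        assert traj.qaly == pytest.approx(10.0, abs=1e-12)
        assert traj.death_month == np.inf

    def test_two_years_at_half_utility_is_one_qaly(self):
        params = make_flat_params(utilities={"ned": 0.5}, horizon=24)
        traj = simulate_patient(
            record(), params, observation_only_policy(),
            rng=np.random.default_rng(0),
        )
        assert traj.ly == pytest.approx(2.0, abs=1e-12)
        assert traj.qaly == pytest.approx(1.0, abs=1e-12)

    def test_event_time_ordering(self, params, policy):
        rng = np.random.default_rng(3)
        for i in range(200):
            traj = simulate_patient(
                record(risk=0.3), params, policy, "usual_care", rng=rng
            )
            times = [traj.bcr_month, traj.met_month, traj.death_month]
            finite = [t for t in times if np.isfinite(t)]
            assert finite == sorted(finite)
            assert traj.qaly <= traj.ly + 1e-12

    def test_occupancy_conserves_time_alive(self, params, policy):
        rng = np.random.default_rng(9)
        for i in range(100):
            traj = simulate_patient(
                record(risk=0.2), params, policy, "gc_based", rng=rng
            )
            months = sum(v[0] for v in traj.occupancy.values())
            qalys = sum(v[1] for v in traj.occupancy.values())
            assert months == pytest.approx(traj.ly * 12, abs=1e-9)
            assert qalys == pytest.approx(traj.qaly, abs=1e-9)


class TestScalarVectorEquivalence:
    def test_routes_bit_identical(self, params, policy):
        n = 250
        rng = np.random.default_rng(42)
        ages = rng.uniform(50, 85, n)
        risks = rng.uniform(0.005, 0.45, n)
        draws = DrawSet.from_rng(np.random.default_rng(7), n, params.horizon_months)
        for arm in ("usual_care", "gc_based"):
            out = simulate_cohort(ages, risks, params, policy, arm, draws)
            for i in range(n):
                rec = PatientRecord(
                    f"p{i}", ages[i], risks[i], risks[i] * 0.6,
                    min(risks[i] * 1.4, 1.0),
                )
                traj = simulate_patient(
                    rec, params, policy, arm, draws=draws.patient(i)
                )
                assert traj.ly == out.ly[i]
                assert traj.qaly == out.qaly[i]
                assert traj.bcr_month == out.bcr_month[i]
                assert traj.met_month == out.met_month[i]
                assert traj.death_month == out.death_month[i]


class TestVectorEngineOracles:
    def test_constant_death_expected_life_years(self):
        # monthly death probability 0.1 => E[months alive] = 10(1-0.9^120)
        n = 50_000
        params = make_flat_params(oc_monthly=0.1)
        draws = DrawSet.from_rng(np.random.default_rng(1), n, 120)
        out = simulate_cohort(
            np.full(n, 65.0), np.zeros(n), params,
            observation_only_policy(), "usual_care", draws,
        )
        expected = 10.0 * (1.0 - 0.9**120) / 12.0
        se = np.sqrt(0.9) / 0.1 / 12.0 / np.sqrt(n)
        assert out.ly.mean() == pytest.approx(expected, abs=3 * se)

    def test_competing_risk_cumulative_incidence_closed_form(self):
        # stationary monthly (death q, metastasis m) from NED only:
        # P(MET by 60) = sum_k [(1-q)(1-m)]^(k-1) (1-q) m
        n = 50_000
        q, m = 0.01, 0.004
        params = make_flat_params(oc_monthly=q, met_ned=m)
        draws = DrawSet.from_rng(np.random.default_rng(2), n, 120)
        out = simulate_cohort(
            np.full(n, 65.0), np.zeros(n), params,
            observation_only_policy(), "usual_care", draws,
        )
        s = (1 - q) * (1 - m)
        analytic = (1 - q) * m * (1 - s**60) / (1 - s)
        p_hat = np.mean(out.met_month <= 60)
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert p_hat == pytest.approx(analytic, abs=3 * se)

    def test_geometric_bcr_incidence(self):
        n = 50_000
        m = 0.0115
        params = make_flat_params(bcr=m)
        draws = DrawSet.from_rng(np.random.default_rng(3), n, 120)
        out = simulate_cohort(
            np.full(n, 65.0), np.zeros(n), params,
            observation_only_policy(), "usual_care", draws,
        )
        analytic = 1 - (1 - m) ** 60
        p_hat = np.mean(out.bcr_month <= 60)
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert p_hat == pytest.approx(analytic, abs=3 * se)


class TestBootstrapComparison:
    def test_identical_arms_zero_deltas(self, params, policy, small_cohort):
        res = run_bootstrap_comparison(
            small_cohort, params, policy,
            Arm("a", "usual_care"), Arm("b", "usual_care"),
            n_samples=4_000, seed=5,
        )
        assert np.all(res.deltas("qaly") == 0.0)
        assert np.all(res.deltas("ly") == 0.0)
        summary = res.summary()
        assert (summary["delta"] == 0.0).all()
        assert (summary["p_value"] == 1.0).all()

    def test_seed_determinism(self, params, policy, small_cohort):
        kw = dict(n_samples=2_000, seed=17)
        a = run_bootstrap_comparison(
            small_cohort, params, policy,
            Arm("u", "usual_care"), Arm("g", "gc_based"), **kw,
        )
        b = run_bootstrap_comparison(
            small_cohort, params, policy,
            Arm("u", "usual_care"), Arm("g", "gc_based"), **kw,
        )
        assert np.array_equal(a.outcomes_b.qaly, b.outcomes_b.qaly)
        assert a.summary().equals(b.summary())

    def test_seed_consistency(self, params, policy, small_cohort):
        runs = [
            run_bootstrap_comparison(
                small_cohort, params, policy,
                Arm("u", "usual_care"), Arm("g", "gc_based"),
                n_samples=8_000, seed=s,
            )
            for s in (1, 2)
        ]
        means = [r.outcomes_b.qaly.mean() for r in runs]
        ses = [r.outcomes_b.qaly.std(ddof=1) / np.sqrt(r.n_samples) for r in runs]
        assert abs(means[0] - means[1]) < 3 * np.hypot(*ses)

    def test_qaly_ci_half_width_at_design_sample_size(
        self, params, policy, small_cohort
    ):
        res = run_bootstrap_comparison(
            small_cohort, params, policy,
            Arm("u", "usual_care"), Arm("g", "gc_based"),
            n_samples=10_000, seed=2,
        )
        for arm in ("a", "b"):
            m, lo, hi = res.mean_ci("qaly", arm)
            assert (hi - lo) / 2 <= 0.1

    def test_ci_contains_point_estimates(self, params, policy, small_cohort):
        res = run_bootstrap_comparison(
            small_cohort, params, policy,
            Arm("u", "usual_care"), Arm("g", "gc_based"),
            n_samples=3_000, seed=4,
        )
        s = res.summary()
        assert ((s["arm_a_lo"] <= s["arm_a"]) & (s["arm_a"] <= s["arm_a_hi"])).all()
        assert ((s["arm_b_lo"] <= s["arm_b"]) & (s["arm_b"] <= s["arm_b_hi"])).all()

    def test_degenerate_inputs_rejected(self, params, policy, small_cohort):
        with pytest.raises(ValueError):
            run_bootstrap_comparison(
                small_cohort, params, policy, Arm("a"), Arm("b"), n_samples=0
            )
        with pytest.raises(ValueError):
            run_bootstrap_comparison(
                small_cohort.iloc[:0], params, policy, Arm("a"), Arm("b")
            )
        with pytest.raises(ValueError, match="r_model"):
            run_bootstrap_comparison(
                small_cohort, params, policy,
                Arm("a"), Arm("b", individualized=True), n_samples=10,
            )


class TestRecurrenceHormoneTherapy:
    def test_treated_patient_restarts_hormones_at_progression(self):
        # force adjuvant RT, then a certain BCR at month 1: the recurrence
        # course must run 24 months of hormone utility
        params = make_flat_params(
            bcr=1.0, utilities={"ht": 0.5}, horizon=40,
            durations=Durations(radiation_months=2, adjuvant_hormone_months=6,
                                salvage_hormone_months=6,
                                recurrence_hormone_months=24),
        )
        traj = simulate_patient(
            record(), params, degenerate_policy("rt"), "usual_care",
            rng=np.random.default_rng(0),
        )
        assert traj.bcr_month == 1
        on_ht = [r for r in traj.records if r.utility == pytest.approx(0.5)]
        assert len(on_ht) == 24
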