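import itertools

import numpy as np
import pytest
from scipy import stats as sps

from gcsim.stats import (
    PairedOutcome,
    event_probability,
    km_estimate,
    km_survival_at,
    mcnemar_from_counts,
    mcnemar_test,
    paired_ttest,
    state_occupancy_summary,
    wald_ci,
)
from gcsim.engine import Arm, run_bootstrap_comparison


class TestWaldCI:
    def test_hand_computed_interval(self):
        lo, hi = wald_ci(0.5, 100)
        assert lo == pytest.approx(0.402, abs=0.0005)
        assert hi == pytest.approx(0.598, abs=0.0005)

    def test_degenerate_at_zero(self):
        assert wald_ci(0.0, 50) == (0.0, 0.0)
        assert wald_ci(1.0, 50) == (1.0, 1.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0)


class TestEventProbability:
    def _outcomes(self):
        from gcsim.engine import CohortOutcomes

        inf = np.inf
        return CohortOutcomes(
            ly=np.ones(4), qaly=np.ones(4),
            bcr_month=np.array([10.0, inf, 30.0, inf]),
            met_month=np.array([inf, inf, 50.0, inf]),
            death_month=np.array([inf, 40.0, 70.0, inf]),
            death_cause=np.array([0, 2, 1, 0]),
            occ_months=np.zeros((4, 3, 3)), occ_qaly=np.zeros((4, 3, 3)),
        )

    def test_event_definitions(self):
        out = self._outcomes()
        p, _, _ = event_probability(out, "bcr", 60)
        assert p == 0.5
        p, _, _ = event_probability(out, "met_or_death", 60)
        assert p == 0.5  # patient 1 died, patient 2 metastasized
        p, _, _ = event_probability(out, "met_or_death", 60, pc_death_only=True)
        assert p == 0.25  # other-cause death no longer counts
        p, _, _ = event_probability(out, "bcr_free_survival", 60)
        assert p == 0.25  # only the last patient is alive and BCR-free

    def test_no_events_degenerate_ci(self):
        out = self._outcomes()
        p, lo, hi = event_probability(out, "bcr", 5)
        assert (p, lo, hi) == (0.0, 0.0, 0.0)

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            event_probability(self._outcomes(), "relapse", 60)


class TestKaplanMeier:
    def test_four_subject_hand_example(self):
        # events at 3 and 5, censored at 4 and 10:
        # S(3) = 3/4, S(5) = 3/4 x 1/2 = 0.375
        km = km_estimate([3, 4, 5, 10], [1, 0, 1, 0])
        assert km_survival_at(km, 3) == pytest.approx(0.75)
        assert km_survival_at(km, 4.5) == pytest.approx(0.75)
        assert km_survival_at(km, 5) == pytest.approx(0.375)
        assert km_survival_at(km, 2) == 1.0

    def test_no_events_flat_at_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.integers(1, 40, 200)
        km = km_estimate(times, np.ones(200))
        for t in (5, 10, 20, 39):
            assert km_survival_at(km, t) == pytest.approx(np.mean(times > t))

    def test_constant_hazard_recovers_geometric_survival(self):
        m, n = 0.02, 30_000
        rng = np.random.default_rng(5)
        times = rng.geometric(m, n)
        censored = np.minimum(times, 120)
        observed = times <= 120
        km = km_estimate(censored, observed)
        target = (1 - m) ** 60
        se = np.sqrt(target * (1 - target) / n)
        assert km_survival_at(km, 60) == pytest.approx(target, abs=3 * se)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestPairedTTest:
    def test_hand_example(self):
        t, p = paired_ttest([0.1, 0.2, 0.3])
        assert t == pytest.approx(3.464, abs=0.001)
        assert p == pytest.approx(0.0742, abs=0.001)

    def test_zero_difference_convention(self):
        assert paired_ttest(np.zeros(100)) == (0.0, 1.0)

    def test_sign_symmetry(self):
        d = np.array([0.05, -0.01, 0.12, 0.03])
        t1, p1 = paired_ttest(d)
        t2, p2 = paired_ttest(-d)
        assert t1 == -t2
        assert p1 == p2

    def test_matches_scipy_on_random_data(self):
        d = np.random.default_rng(0).normal(0.01, 0.1, 500)
        t, p = paired_ttest(d)
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([0.1])


def brute_force_mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p by enumerating all 2^(b+c) equally
    likely splits of the discordant pairs under the null."""
    n = b + c
    observed = min(b, c)
    hits = 0
    for combo in itertools.product([0, 1], repeat=n):
        k = sum(combo)
        if min(k, n - k) <= observed:
            hits += 1
    return min(hits / 2**n, 1.0)


class TestMcNemar:
    def test_chi2_statistic_by_hand(self):
        stat, p, method = mcnemar_from_counts(5, 10, exact_threshold=2)
        assert method == "chi2"
        assert stat == pytest.approx((5 - 10) ** 2 / 15)
        assert p == pytest.approx(sps.chi2.sf(stat, 1))

    def test_symmetric_counts_give_p_one(self):
        stat, p, _ = mcnemar_from_counts(7, 7, exact_threshold=2)
        assert stat == 0.0
        assert p == 1.0

    def test_no_discordance_convention(self):
        assert mcnemar_from_counts(0, 0)[1] == 1.0

    @pytest.mark.parametrize("b,c", [(2, 5), (0, 6), (3, 3), (1, 10)])
    def test_exact_p_matches_brute_force_enumeration(self, b, c):
        _, p, method = mcnemar_from_counts(b, c)
        assert method == "exact"
        assert p == pytest.approx(brute_force_mcnemar_exact(b, c), abs=1e-12)

    def test_exact_and_chi2_agree_asymptotically(self):
        b, c = 460, 520
        _, p_chi2, _ = mcnemar_from_counts(b, c, exact_threshold=2)
        _, p_exact, _ = mcnemar_from_counts(b, c, exact_threshold=10_000)
        assert p_chi2 == pytest.approx(p_exact, rel=0.15)

    def test_array_interface(self):
        a = np.array([1, 1, 0, 0, 1, 0])
        b = np.array([1, 0, 1, 0, 0, 1])
        stat, p, _ = mcnemar_test(a, b)
        # discordant: b=2 (A only), c=2 (B only)
        assert p == pytest.approx(brute_force_mcnemar_exact(2, 2), abs=1e-12)


class TestPairedOutcome:
    def test_deltas_and_validation(self):
        po = PairedOutcome(np.array([1.0, 2.0]), np.array([1.5, 1.0]))
        assert np.allclose(po.deltas, [0.5, -1.0])
        with pytest.raises(ValueError):
            PairedOutcome(np.zeros(2), np.zeros(3))


class TestOccupancy:
    def test_zero_event_cohort_all_time_in_ned(self, policy):
        from .conftest import make_cohort, make_flat_params, observation_only_policy

        params = make_flat_params()
        cohort = make_cohort([64.0] * 10, [0.05] * 10)
        res = run_bootstrap_comparison(
            cohort, params, observation_only_policy(),
            Arm("a"), Arm("b"), n_samples=500, seed=0,
        )
        df = state_occupancy_summary(res.outcomes_a)
        ned = df[(df["state"] == "NED") & (df["treatment"] == "untreated")]
        assert ned["ly"].iloc[0] == pytest.approx(10.0)
        total = df[df["state"] == "TOTAL"]
        assert total["ly"].iloc[0] == pytest.approx(10.0)

    def test_totals_reconcile_with_means(self, params, policy, small_cohort):
        res = run_bootstrap_comparison(
            small_cohort, params, policy,
            Arm("u", "usual_care"), Arm("g", "gc_based"),
            n_samples=2_000, seed=6,
        )
        for out in (res.outcomes_a, res.outcomes_b):
            df = state_occupancy_summary(out)
            total = df[df["state"] == "TOTAL"].iloc[0]
            assert total["ly"] == pytest.approx(out.ly.mean(), abs=1e-9)
            assert total["qaly"] == pytest.approx(out.qaly.mean(), abs=1e-9)
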