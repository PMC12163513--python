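import numpy as np
import pytest

from morphohet.survival import (
    _two_group_logrank_stat,
    km_estimate,
    logrank_test,
    optimal_cutoff,
    stratified_survival_report,
)
from morphohet.simulate import SimConfig, simulate_cohort_frame
from morphohet.types import ValidationError

from conftest import logrank_oe, product_limit


class TestKaplanMeier:
    def test_all_censored_curve_is_constant_one(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_two_subjects_two_events_by_hand(self):
        curve = km_estimate([1, 2], [1, 1])
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_matches_hand_product_limit_on_random_data(self, rng):
        for _ in range(100):
            n = rng.integers(3, 60)
            times = np.round(rng.exponential(10, size=n), 1)
            events = rng.integers(0, 2, size=n)
            curve = km_estimate(times, events)
            lookup = dict(zip(curve["time"], curve["survival"]))
            for t, s in product_limit(times, events):
                assert lookup[t] == pytest.approx(s, abs=1e-10)

    def test_curve_starts_at_one_and_never_increases(self, rng):
        times = rng.exponential(10, size=50)
        events = rng.integers(0, 2, size=50)
        curve = km_estimate(times, events)
        assert curve["survival"].iloc[0] <= 1.0 + 1e-12
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survivor_function(self, rng):
        times = rng.exponential(10, size=40)
        curve = km_estimate(times, np.ones(40, dtype=int))
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx(np.mean(times > t), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = np.tile([1.0, 3.0, 5.0, 8.0], 2)
        events = np.tile([1, 0, 1, 1], 2)
        groups = np.repeat(["a", "b"], 4)
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(10, size=60)
        events = rng.integers(0, 2, size=60)
        groups = rng.choice(["a", "b"], size=60)
        s1, _ = logrank_test(times, events, groups)
        swapped = np.where(groups == "a", "b", "a")
        s2, _ = logrank_test(times, events, swapped)
        assert s1 == pytest.approx(s2)

    def test_internal_oe_statistic_matches_public_test_and_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(10, 80)
            times = np.round(rng.exponential(10, size=n), 1)
            events = rng.integers(0, 2, size=n)
            g1 = rng.integers(0, 2, size=n).astype(bool)
            if g1.all() or not g1.any() or events.sum() == 0:
                continue
            fast = _two_group_logrank_stat(times, events.astype(float), g1.astype(float))
            oracle = logrank_oe(times, events, g1)
            assert fast == pytest.approx(oracle, abs=1e-9)
            stat, _ = logrank_test(times, events, np.where(g1, "hi", "lo"))
            assert fast == pytest.approx(stat, abs=1e-8)

    def test_hazard_ratio_three_is_detected(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            t1 = rng.exponential(1.0, size=100)
            t2 = rng.exponential(1 / 3, size=100)
            times = np.concatenate([t1, t2])
            events = np.ones(200, dtype=int)
            _, p = logrank_test(times, events, np.repeat(["a", "b"], 100))
            hits += p < 0.01
        assert hits / reps >= 0.95

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestOptimalCutoff:
    def test_planted_changepoint_recovered(self, rng):
        n = 200
        x = rng.uniform(size=n)
        hazard = np.where(x > 0.6, 1.0, 0.1)
        times = rng.exponential(1 / hazard)
        strat = optimal_cutoff(x, times, np.ones(n, dtype=int))
        distinct = np.unique(x)
        step = np.diff(distinct).max()
        assert abs(strat.cutoff - 0.6) <= 2 * step
        assert strat.exploratory

    def test_min_leaf_half_only_allows_median_split(self, rng):
        x = np.arange(10) / 10
        times = rng.exponential(1, size=10)
        strat = optimal_cutoff(x, times, np.ones(10, dtype=int), min_leaf_frac=0.5)
        assert strat.cutoff == pytest.approx(0.45)  # the unique 5/5 midpoint
        assert strat.n_low == strat.n_high == 5

    def test_constant_proportions_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            optimal_cutoff(np.ones(20), np.arange(1, 21), np.ones(20, dtype=int))

    def test_deterministic_given_inputs(self, rng):
        x = rng.uniform(size=80)
        times = rng.exponential(1, size=80)
        events = rng.integers(0, 2, size=80)
        a = optimal_cutoff(x, times, events)
        b = optimal_cutoff(x.copy(), times.copy(), events.copy())
        assert a.cutoff == b.cutoff
        assert a.logrank_statistic == b.logrank_statistic

    def test_null_proportions_show_selection_bias(self, rng):
        # the maximally-separating split inflates naive significance: the
        # post-selection p<0.05 rate far exceeds 5% on pure noise
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 80
            x = rng.uniform(size=n)
            times = rng.exponential(1, size=n)
            strat = optimal_cutoff(x, times, np.ones(n, dtype=int))
            hits += strat.logrank_p < 0.05
        assert hits / reps > 0.15


class TestStratifiedReport:
    def test_stage_subset_and_full_grid(self):
        cohort, _ = simulate_cohort_frame(SimConfig(n_tumors=80, seed=5))
        strata = stratified_survival_report(cohort)
        assert len(strata) == 3 * 2 * 2  # variables x endpoints x subsets
        n_stage13 = int((cohort["ajcc_stage"] != "IV").sum())
        for s in strata:
            if s.subset == "stage I-III":
                assert s.n_low + s.n_high == n_stage13
            curves = s.km_curves
            assert set(curves) == {"low", "high"}

    def test_planted_de_hazard_lowers_high_arm_curve(self):
        cohort, _ = simulate_cohort_frame(SimConfig(n_tumors=161, seed=17))
        strata = stratified_survival_report(cohort, variables=("p_DE",),
                                            endpoints=("OS",), subsets=("all",))
        s = strata[0]
        assert s.logrank_p < 0.05
        # high-DE arm should end lower than the low-DE arm
        assert (s.km_curves["high"]["survival"].iloc[-1]
                < s.km_curves["low"]["survival"].iloc[-1])

    def test_missing_endpoint_column_rejected(self):
        cohort, _ = simulate_cohort_frame(SimConfig(n_tumors=40, seed=2))
        with pytest.raises(ValidationError):
            stratified_survival_report(cohort.drop(columns=["os_time"]),
                                       endpoints=("OS",))
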