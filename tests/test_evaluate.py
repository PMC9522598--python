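import numpy as np
import pandas as pd
import pytest

from iprp.evaluate import (
    EvaluationError,
    concordance_index,
    cross_cohort_distribution_test,
    km_estimate,
    logrank_test,
    permutation_test_auc,
    time_dependent_auc,
)
from tests.conftest import make_survival


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        est = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(est.survival, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        est = km_estimate([5.0, 10.0, 15.0], [0, 0, 0])
        assert (est.survival == 1.0).all()

    def test_single_event_steps_to_zero(self):
        est = km_estimate([1.0], [1])
        assert est.survival_at(0.5) == 1.0
        assert est.survival_at(1.0) == 0.0

    def test_monotone_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(0)
        times, events = make_survival(rng, np.zeros(100))
        est = km_estimate(times, events)
        assert (np.diff(est.survival) <= 1e-12).all()
        assert est.survival[0] == 1.0
        assert ((est.survival >= 0) & (est.survival <= 1)).all()

    def test_negative_times_rejected(self):
        with pytest.raises(EvaluationError):
            km_estimate([-1.0, 2.0], [1, 1])


def _oe_logrank(groups, times, events):
    """Direct observed/expected/variance summation (two groups)."""
    groups = np.asarray(groups)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    gset = np.unique(groups)
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & (groups == gset[0])).sum()
        d1 = ((times == t) & (events == 1) & (groups == gset[0])).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_null(self):
        times = np.r_[np.linspace(10, 100, 20), np.linspace(10, 100, 20)]
        groups = np.r_[np.zeros(20), np.ones(20)]
        chi2, p = logrank_test(groups, times, np.ones(40, int))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_direct_oe_summation(self):
        times = [3.0, 5.0, 7.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        chi2, _ = logrank_test(groups, times, events)
        assert chi2 == pytest.approx(_oe_logrank(groups, times, events), rel=1e-9)

    def test_planted_hazard_ratio_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            group = rng.integers(0, 2, 300)
            times, events = make_survival(rng, np.log(3.0) * group)
            _, p = logrank_test(group, times, events)
            hits += p < 1e-3
        assert hits >= 19

    def test_single_group_rejected(self):
        with pytest.raises(EvaluationError):
            logrank_test(np.zeros(5), np.arange(1.0, 6.0), np.ones(5, int))


class TestTimeDependentAuc:
    def test_perfect_ranking_auc_one(self):
        times = np.linspace(1, 100, 50)
        scores = -times  # higher risk = earlier event
        roc = time_dependent_auc(scores, times, np.ones(50, int), horizon=50.0)
        assert roc.auc == pytest.approx(1.0)

    def test_constant_score_auc_half(self):
        times = np.linspace(1, 100, 50)
        roc = time_dependent_auc(np.zeros(50), times, np.ones(50, int), horizon=50.0)
        assert roc.auc == pytest.approx(0.5)

    def test_random_score_near_half(self):
        rng = np.random.default_rng(1)
        times, events = make_survival(rng, np.zeros(500))
        roc = time_dependent_auc(rng.normal(size=500), times, events,
                                 horizon=float(np.median(times)))
        assert abs(roc.auc - 0.5) < 0.05

    def test_matches_sksurv_estimator(self):
        """Independent cross-check against scikit-survival's IPCW cumulative/dynamic AUC."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(2)
        scores = rng.normal(size=300)
        times, events = make_survival(rng, 0.8 * scores)
        y = Surv.from_arrays(event=events.astype(bool), time=times)
        horizon = float(np.quantile(times, 0.4))
        theirs, _ = cumulative_dynamic_auc(y, y, scores, [horizon])
        ours = time_dependent_auc(scores, times, events, horizon).auc
        assert ours == pytest.approx(float(theirs[0]), abs=1e-8)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        times, events = make_survival(rng, scores)
        h = float(np.median(times))
        a1 = time_dependent_auc(scores, times, events, h).auc
        a2 = time_dependent_auc(np.exp(2 * scores), times, events, h).auc
        assert a1 == pytest.approx(a2)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=200)
        times, events = make_survival(rng, scores)
        roc = time_dependent_auc(scores, times, events, float(np.median(times)))
        assert (np.diff(roc.sensitivity) >= -1e-12).all()
        assert (np.diff(roc.specificity) <= 1e-12).all()

    def test_no_cases_or_controls_rejected(self):
        times = np.linspace(10, 20, 10)
        with pytest.raises(EvaluationError):
            time_dependent_auc(np.zeros(10), times, np.ones(10, int), horizon=5.0)
        with pytest.raises(EvaluationError):
            time_dependent_auc(np.zeros(10), times, np.ones(10, int), horizon=25.0)


class TestPermutationTest:
    def test_perfect_score_attains_minimum_p(self):
        times = np.linspace(1, 200, 200)
        p = permutation_test_auc(-times, times, np.ones(200, int), horizon=100.0,
                                 n_perm=200, seed=0)
        assert p == pytest.approx(1.0 / 201.0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(EvaluationError):
            permutation_test_auc(np.zeros(10), np.arange(1.0, 11.0), np.ones(10, int),
                                 horizon=5.0, n_perm=0)


class TestConcordance:
    def test_perfect_anti_ranking_zero(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        scores = times.copy()  # lowest risk dies first = fully discordant
        assert concordance_index(scores, times, np.ones(4, int)) == 0.0

    def test_three_sample_brute_force(self):
        times = np.array([2.0, 5.0, 9.0])
        events = np.array([1, 1, 0])
        scores = np.array([3.0, 1.0, 2.0])
        # comparable pairs: (0,1) concordant, (0,2) concordant, (1,2) discordant
        assert concordance_index(scores, times, events) == pytest.approx(2 / 3)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        times, events = make_survival(rng, np.zeros(1000))
        c = concordance_index(rng.normal(size=1000), times, events)
        assert abs(c - 0.5) < 0.05


class TestCrossCohortAnova:
    def test_identical_vectors_give_zero_f(self):
        v = np.array([0.4, 0.8, 1.2, 1.6])
        F, p = cross_cohort_distribution_test({"a": v, "b": v.copy(), "c": v.copy()})
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_shifted_cohort_detected(self):
        rng = np.random.default_rng(6)
        F, p = cross_cohort_distribution_test(
            {"a": rng.normal(1, 0.3, 50), "b": rng.normal(1, 0.3, 50) + 10.0}
        )
        assert p < 1e-10

    def test_single_cohort_rejected(self):
        with pytest.raises(EvaluationError):
            cross_cohort_distribution_test({"a": np.ones(5)})
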