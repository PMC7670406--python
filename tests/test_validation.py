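"""Validation metrics against hand calculations and brute-force oracles."""

import numpy as np
import pytest

from agingnet.likelihood import CohortRecord, SurvivalCurve
from agingnet.model import HealthState, ModelHyperparameters, ModelParameters
from agingnet.simulate import RngSpec, Trajectory, simulate_cohort
from agingnet.validation import (MetricResult, brier_r2, conditional_damage_rate,
                                 deficit_prevalence, fi_distribution,
                                 kaplan_meier, leftout_deficit_auc,
                                 mean_survival_curve, pairwise_prevalence,
                                 td_c_index, window_mortality_auc)

from conftest import constant_rate_params, two_node_params


def _traj(n, start=0.0, events=(), death=None, horizon=120.0, initial=None):
    init = HealthState(np.zeros(n, dtype=int) if initial is None
                       else np.asarray(initial), start)
    return Trajectory(start, init, list(events), death, horizon)


class TestPrevalence:
    def test_zero_rate_cohort_is_zero_everywhere(self):
        trajs = [_traj(2) for _ in range(20)]
        for c in deficit_prevalence(trajs, np.arange(0, 100, 10.0)):
            assert np.allclose(c.values, 0.0)

    def test_static_half_damaged(self):
        trajs = [_traj(1, initial=[1]) for _ in range(10)] + \
                [_traj(1) for _ in range(10)]
        (c,) = deficit_prevalence(trajs, np.array([10.0, 50.0]))
        assert np.allclose(c.values, 0.5)

    def test_single_node_closed_form(self):
        lam = 0.05
        p = constant_rate_params(lam)
        trajs = simulate_cohort(p, [HealthState(np.array([0]), 0.0)],
                                rng=RngSpec(1), replicates_per_baseline=8000)
        ages = np.array([10.0, 30.0, 60.0])
        (c,) = deficit_prevalence(trajs, ages)
        ref = 1 - np.exp(-lam * ages)
        assert np.all(np.abs(c.values - ref) <
                      3 * np.sqrt(ref * (1 - ref) / 8000))

    def test_pairwise_independent_is_product(self):
        p = two_node_params(0.04, 0.07)   # no coupling, no mortality
        trajs = simulate_cohort(p, [HealthState(np.zeros(2, int), 0.0)],
                                rng=RngSpec(2), replicates_per_baseline=8000)
        ages = np.array([20.0, 40.0])
        joint = pairwise_prevalence(trajs, ages, (0, 1))
        p1 = 1 - np.exp(-0.04 * ages)
        p2 = 1 - np.exp(-0.07 * ages)
        assert np.all(np.abs(joint.values - p1 * p2) < 0.03)
        # Frechet bounds
        m = deficit_prevalence(trajs, ages)
        lo = np.maximum(0, m[0].values + m[1].values - 1)
        hi = np.minimum(m[0].values, m[1].values)
        assert np.all(joint.values >= lo - 1e-12)
        assert np.all(joint.values <= hi + 1e-12)

    def test_pairwise_coupled_equals_marginal(self):
        trajs = [_traj(2, initial=[1, 1]) for _ in range(10)] + \
                [_traj(2) for _ in range(10)]
        joint = pairwise_prevalence(trajs, np.array([5.0]), (0, 1))
        assert joint.values[0] == pytest.approx(0.5)

    def test_pairwise_disjoint_is_zero(self):
        trajs = [_traj(2, initial=[1, 0]) for _ in range(5)] + \
                [_traj(2, initial=[0, 1]) for _ in range(5)]
        joint = pairwise_prevalence(trajs, np.array([5.0]), (0, 1))
        assert joint.values[0] == 0.0


class TestFiDistribution:
    def test_point_masses(self):
        support, probs = fi_distribution([_traj(10) for _ in range(7)], 20.0)
        assert probs[0] == 1.0 and probs.sum() == pytest.approx(1.0)
        one = np.zeros(10, int)
        one[4] = 1
        support, probs = fi_distribution(
            [_traj(10, initial=one) for _ in range(7)], 20.0)
        assert probs[1] == 1.0
        assert support[1] == pytest.approx(0.1)


def _brute_force_auc(scores, labels):
    """Probability a positive outranks a negative (ties 0.5)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLeftoutAuc:
    def test_informative_network_beats_chance(self):
        # strong coupling 1 -> 0 and no age signal: knowing d_1 helps d_0
        p = two_node_params(0.01, 0.05, w12=3.0)
        records = []
        trajs = simulate_cohort(p, [HealthState(np.zeros(2, int), 0.0)],
                                rng=RngSpec(3), replicates_per_baseline=400)
        for tr in trajs:
            d = (np.array([a for a, _ in tr.events] + [np.inf, np.inf])[:2]
                 if False else None)
            st = np.zeros(2)
            for age, node in tr.events:
                if age <= 40.0:
                    st[node] = 1
            records.append(CohortRecord(40.0, st, 41.0, 1))
        res = leftout_deficit_auc(p, records, leftout=0, n_sim=4000,
                                  rng=RngSpec(4))
        assert res[0].estimate > 0.5
        assert res[0].ci_low > 0.5

    def test_auc_toy_examples(self):
        assert _brute_force_auc([0.9, 0.8, 0.1], [1, 0, 0]) == 1.0
        assert _brute_force_auc([0.8, 0.9, 0.1], [1, 0, 0]) == 0.5
        rng = np.random.default_rng(5)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, s) == pytest.approx(_brute_force_auc(s, y))


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert float(km.survival_function_at_times(2.5).iloc[0]) == \
            pytest.approx(1 / 3)

    def test_all_censored_flat(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        assert float(km.survival_function_at_times(3.0).iloc[0]) == 1.0

    def test_product_limit_with_censoring(self):
        # deaths at 1 and 3, censored at 2:
        # S(2.5) = (1 - 1/3) = 2/3 ; S(3+) = 2/3 * (1 - 1/1) = 0
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 1, 0])
        assert float(km.survival_function_at_times(2.5).iloc[0]) == \
            pytest.approx(2 / 3)
        assert float(km.survival_function_at_times(3.5).iloc[0]) == 0.0


class TestMeanSurvival:
    def test_identical_records_equal_individual_curve(self):
        p = constant_rate_params(0.0, mort=0.05)
        recs = [CohortRecord(50.0, np.array([0.0]), 56.0, 1)] * 3
        ages, vals = mean_survival_curve(p, recs, n_sim=400, rng=RngSpec(6),
                                         ages=np.arange(50, 90.0))
        from agingnet.likelihood import survival_function
        single = survival_function(p, recs[0], 400, RngSpec(6))
        assert np.allclose(vals, single(np.arange(50, 90.0)), atol=0.05)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_mixture_with_instant_death(self):
        slow = SurvivalCurve(60.0, np.full(100, np.inf), 120.0)
        fast = SurvivalCurve(60.0, np.full(100, 60.01), 120.0)
        mix = 0.5 * (slow(np.array([70.0])) + fast(np.array([70.0])))
        assert mix[0] == pytest.approx(0.5)


def _brute_force_c_td(curves, a, c):
    num = den = 0.0
    for i in range(len(a)):
        if c[i] == 1:
            continue
        for j in range(len(a)):
            if a[j] <= a[i]:
                continue
            den += 1
            si, sj = curves[i](a[i]), curves[j](a[i])
            num += 1.0 if si < sj else 0.5 if si == sj else 0.0
    return num / den if den else np.nan


def _curve_from_deaths(start, deaths):
    return SurvivalCurve(start, np.asarray(deaths, float), 120.0)


class TestTdCIndex:
    def test_perfectly_ordered_predictions(self):
        # predicted death ages 69/74/79 track true death ages 70/75/80:
        # at every earlier death age the earlier-dying individual's curve
        # has already dropped while the later one's has not
        a = np.array([70.0, 75.0, 80.0])
        c = np.zeros(3, int)
        curves = [_curve_from_deaths(65, [69 + 5 * k] * 50) for k in range(3)]
        res = td_c_index(curves, a, c, n_boot=50)
        assert res[0].estimate == 1.0

    def test_identical_predictions_all_ties(self):
        a = np.array([70.0, 75.0, 80.0])
        c = np.zeros(3, int)
        curves = [_curve_from_deaths(65, [90] * 50)] * 3
        res = td_c_index(curves, a, c, n_boot=50)
        assert res[0].estimate == 0.5

    def test_hand_enumerated_three_individuals(self):
        a = np.array([70.0, 75.0, 80.0])
        c = np.array([0, 0, 0])
        curves = [_curve_from_deaths(65, [72, 73, 74, 90]),
                  _curve_from_deaths(65, [70, 71, 72, 73]),
                  _curve_from_deaths(65, [85, 88, 90, 95])]
        # pairs: (0,1): S0(70)=1 vs S1(70)=0.75 -> discordant (0)
        #        (0,2): S0(70)=1 vs S2(70)=1    -> tie (0.5)
        #        (1,2): S1(75)=0  vs S2(75)=1   -> concordant (1)
        res = td_c_index(curves, a, c, n_boot=50)
        assert res[0].estimate == pytest.approx(1.5 / 3)
        assert res[0].estimate == pytest.approx(_brute_force_c_td(curves, a, c))

    def test_matches_brute_force_with_censoring_and_strata(self, rng):
        M = 40
        t0 = rng.uniform(60, 90, M)
        a = t0 + rng.uniform(0.5, 10, M)
        c = rng.integers(0, 2, M)
        curves = [_curve_from_deaths(t0[i], t0[i] + rng.exponential(8, 60))
                  for i in range(M)]
        res = td_c_index(curves, a, c, age_strata=[60, 75, 90],
                         baseline_ages=t0, n_boot=50)
        assert res[0].estimate == pytest.approx(_brute_force_c_td(curves, a, c))
        for r, (lo, hi) in zip(res[1:], [(60, 75), (75, 90)]):
            sel = (t0 >= lo) & (t0 < hi)
            ref = _brute_force_c_td([cv for cv, s in zip(curves, sel) if s],
                                    a[sel], c[sel])
            assert r.estimate == pytest.approx(ref, nan_ok=True)


class TestBrierR2:
    def test_reference_model_scores_zero(self):
        a = np.array([70.0, 75.0, 80.0, 85.0])
        c = np.zeros(4, int)
        km = kaplan_meier(a, c)
        t = 77.0
        s_km = float(km.survival_function_at_times(t).iloc[0])
        curves = [SurvivalCurve(60.0, np.full(100, np.inf), 120.0)] * 4
        # build curves that all equal the KM value at t
        k = int(round(s_km * 100))
        deaths = np.concatenate([np.full(100 - k, 70.0), np.full(k, np.inf)])
        curves = [SurvivalCurve(60.0, deaths, 120.0)] * 4
        res = brier_r2(curves, a, c, [t], n_boot=50)
        assert res[0].estimate == pytest.approx(0.0, abs=1e-9)

    def test_perfect_predictions_no_censoring(self):
        a = np.array([70.0, 75.0, 85.0, 90.0])
        c = np.zeros(4, int)
        curves = [_curve_from_deaths(60.0, [ai] * 50) for ai in a]
        res = brier_r2(curves, a, c, [80.0], n_boot=50)
        assert res[0].estimate == pytest.approx(1.0)

    def test_toy_direct_formula(self):
        # no censoring: G = 1 everywhere; eval at t = 80
        a = np.array([70.0, 75.0, 85.0, 90.0])
        c = np.zeros(4, int)
        s_at_80 = [0.2, 0.4, 0.9, 0.7]
        curves = [_curve_from_deaths(60.0, [79.0] * int(round((1 - s) * 100))
                                     + [inf] * int(round(s * 100)))
                  for s, inf in zip(s_at_80, [np.inf] * 4)]
        km = kaplan_meier(a, c)
        s_ref = float(km.survival_function_at_times(80.0).iloc[0])
        bs_model = np.mean([0.2 ** 2, 0.4 ** 2, (1 - 0.9) ** 2, (1 - 0.7) ** 2])
        bs_ref = np.mean([s_ref ** 2, s_ref ** 2,
                          (1 - s_ref) ** 2, (1 - s_ref) ** 2])
        res = brier_r2(curves, a, c, [80.0], n_boot=50)
        assert res[0].estimate == pytest.approx(1 - bs_model / bs_ref)


class TestWindowAuc:
    def test_degenerate_labels_signalled(self):
        p = constant_rate_params(0.0)    # nobody ever dies
        recs = [CohortRecord(60.0, np.array([0.0]), 70.0, 1)] * 4
        with pytest.raises(ValueError, match="undefined"):
            window_mortality_auc(p, recs, 5.0, n_sim=20, rng=RngSpec(7))

    def test_perfect_separation_on_toy(self):
        # mortality depends strongly on the deficit
        h = ModelHyperparameters(n=1, n_f=0, n_plus=0, n_d1=1, n_d2=0)
        p = ModelParameters(hyper=h, w=np.zeros((1, 1)), mu=np.zeros((1, 0)),
                            gamma=np.array([[0.0]]), beta=np.array([5.0]),
                            alpha=np.array([0.0, 1.0]), eta=np.array([0.001]))
        recs = [CohortRecord(60.0, np.array([1.0]), 61.0, 0),
                CohortRecord(60.0, np.array([1.0]), 62.0, 0),
                CohortRecord(60.0, np.array([0.0]), 65.0, 1),
                CohortRecord(60.0, np.array([0.0]), 65.0, 1)]
        res = window_mortality_auc(p, recs, 5.0, n_sim=100, rng=RngSpec(8))
        assert res.estimate == 1.0

    def test_matches_brute_force(self):
        m = 0.08
        p = constant_rate_params(0.0, mort=m)
        rng = np.random.default_rng(9)
        recs = []
        for _ in range(30):
            t = rng.uniform(60, 80)
            td = t + rng.exponential(1 / m)
            a, c = (td, 0) if td < t + 6 else (t + 6, 1)
            recs.append(CohortRecord(t, np.array([0.0]), a, c))
        try:
            res = window_mortality_auc(p, recs, 5.0, n_sim=150, rng=RngSpec(10))
        except ValueError:
            pytest.skip("degenerate draw")
        from agingnet.validation import predict_survival_curves
        curves = predict_survival_curves(p, recs, 150, RngSpec(10))
        scores, labels = [], []
        for r, cv in zip(recs, curves):
            end = r.baseline_age + 5.0
            if r.censored == 1 and r.survival_age < end:
                continue
            labels.append(int(r.censored == 0 and r.survival_age <= end))
            scores.append(1.0 - cv(end))
        assert res.estimate == pytest.approx(_brute_force_auc(scores, labels))


class TestConditionalDamageRate:
    def test_zero_weights_equal_marginal(self):
        p = two_node_params(0.03, 0.04)
        curve = conditional_damage_rate(p, source=1, target=0,
                                        ages=[10.0, 30.0], n_sim=2000,
                                        rng=RngSpec(11))
        assert np.allclose(curve, 0.03, atol=1e-12)

    def test_positive_weight_raises_conditional_rate(self):
        base = two_node_params(0.03, 0.04)
        coupled = two_node_params(0.03, 0.04, w12=2.0)
        ages = [20.0, 40.0]
        a = conditional_damage_rate(base, 1, 0, ages, 2000, RngSpec(12))
        b = conditional_damage_rate(coupled, 1, 0, ages, 2000, RngSpec(12))
        assert np.all(b > a)

    def test_two_node_enumeration(self):
        # with only two nodes there are no remaining deficits to average over:
        # Gamma_{0<-1} = hinge(gamma_00 + gamma_01 * hinge(w_01))
        p = two_node_params(0.02, 0.05, w12=0.7)
        curve = conditional_damage_rate(p, 1, 0, [15.0], 3000, RngSpec(13))
        assert curve[0] == pytest.approx(0.02 + 0.7, rel=1e-9)


def test_metric_result_invariant():
    with pytest.raises(ValueError):
        MetricResult(0.9, 0.1, 0.5)
    r = MetricResult(0.6, 0.5, 0.7, stratum="all", n=10)
    assert r.ci_low <= r.estimate <= r.ci_high
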