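"""Patient-test checks: enumeration/closed-form oracles for SoF and ExprSL,
product-limit arithmetic for the reference curve, and the fitness LRT."""

import numpy as np
import pytest
from scipy import stats as sps

from slidekit.datatypes import GenePair, SurvivalRecord
from slidekit.patient import (
    estimate_reference_survival,
    exprsl,
    fit_group_fitness,
    isurvlrt,
    sof,
    survlrt,
)
from slidekit.simulate import draw_survival, exponential_reference


class TestSoF:
    def test_most_extreme_arrangement(self):
        r = sof([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.p_value == pytest.approx(1 / 20)

    def test_identical_distribution(self):
        r = sof([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.p_value >= 0.5

    def test_reversed_direction(self):
        r = sof([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0])
        assert r.p_value >= 0.95

    def test_empty_group_inapplicable(self):
        assert not sof([1, 2, 3], [0, 0, 0]).applicable


class TestExprSL:
    def test_hand_computed_spearman(self):
        # rank-difference formula: rho = 1 - 6*2/(5*24) = 0.9
        r = exprsl([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert r.extra["rho"] == pytest.approx(0.9)
        t = 0.9 * np.sqrt(3 / (1 - 0.81))
        assert r.p_value == pytest.approx(2 * sps.t.sf(t, df=3))

    def test_perfect_monotone_is_degenerate(self):
        r = exprsl([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.extra["rho"] == 1.0 and r.p_value == 0.0 and r.extra["degenerate"]
        r = exprsl([1, 2, 3, 4], [40, 30, 20, 10])
        assert r.extra["rho"] == -1.0

    def test_constant_vector_inapplicable(self):
        assert not exprsl([1, 1, 1, 1], [1, 2, 3, 4]).applicable

    def test_too_few_observations_inapplicable(self):
        assert not exprsl([1, 2, 3], [3, 1, 2]).applicable


class TestReferenceSurvival:
    def test_product_limit_no_censoring(self):
        # 4 unique death times: S drops by 1/4 per event, hand-computed
        records = [SurvivalRecord(f"p{i}", t, 1) for i, t in enumerate([1, 2, 3, 4])]
        ref = estimate_reference_survival(records)
        assert ref.evaluate(0.0) == pytest.approx(1.0)
        assert ref.evaluate(1.0) == pytest.approx(3 / 4)
        assert ref.evaluate(2.5) == pytest.approx(2 / 4)
        assert ref.evaluate(10.0) == pytest.approx(ref.floor, abs=1e-9)

    def test_all_censored_is_an_error(self):
        records = [SurvivalRecord("p1", 5.0, 0), SurvivalRecord("p2", 7.0, 0)]
        with pytest.raises(ValueError, match="no events"):
            estimate_reference_survival(records)

    def test_survival_floored_for_finite_logs(self):
        records = [SurvivalRecord("p1", 1.0, 1), SurvivalRecord("p2", 2.0, 1)]
        ref = estimate_reference_survival(records)
        assert np.isfinite(ref.neg_log([100.0])).all()


class TestFitGroupFitness:
    def test_single_event_closed_form(self):
        ref = exponential_reference(1.0, t_max=20, n_steps=200001)
        # -ln S(t) = t; one event at t = 1 -> Delta = 1
        assert fit_group_fitness([1.0], [1], ref) == pytest.approx(1.0, rel=1e-3)

    def test_neutral_fitness(self):
        ref = exponential_reference(1.0, t_max=20, n_steps=200001)
        times = [0.5, 1.0, 1.5]  # sum -ln S = 3 with 3 events -> Delta = 1
        assert fit_group_fitness(times, [1, 1, 1], ref) == pytest.approx(1.0, rel=1e-3)

    def test_no_events_not_estimable(self):
        ref = exponential_reference(1.0)
        with pytest.raises(ValueError, match="no events"):
            fit_group_fitness([1.0, 2.0], [0, 0], ref)

    def test_recovers_planted_fitness(self):
        ref = exponential_reference(0.02, t_max=3000, n_steps=30000)
        rng = np.random.default_rng(11)
        times, events = draw_survival(rng, np.full(2000, np.log(2.0)), 0.02, 0.0)
        assert fit_group_fitness(times, events, ref) == pytest.approx(2.0, rel=0.05)


def make_genotype_data(seed, deltas, n_per_group=150, censoring=0.3):
    rng = np.random.default_rng(seed)
    ga = np.repeat([0, 0, 1, 1], n_per_group)
    gb = np.tile(np.repeat([0, 1], n_per_group), 2)
    lf = np.array([deltas[(a, b)] for a, b in zip(ga, gb)])
    times, events = draw_survival(rng, lf, 0.02, censoring)
    return ga, gb, times, events


class TestSurvLRT:
    ref = exponential_reference(0.02, t_max=5000, n_steps=50000)

    def test_effect_size_arithmetic_and_flags(self):
        deltas = {(0, 0): 0.0, (0, 1): -1.0, (1, 0): -1.0, (1, 1): -3.0}
        ga, gb, t, e = make_genotype_data(0, deltas, n_per_group=400, censoring=0.0)
        r = survlrt(ga, gb, t, e, self.ref)
        d = r.delta_hat
        assert r.effect_size == pytest.approx(
            d[(0, 0)] + d[(1, 1)] - d[(0, 1)] - d[(1, 0)]
        )
        assert r.delta11_expected == pytest.approx(
            d[(0, 1)] + d[(1, 0)] - d[(0, 0)]
        )
        # planted effect: delta = 0 + (-3) - (-1) - (-1) = -1 < 0
        assert r.effect_size == pytest.approx(-1.0, abs=0.3)
        assert r.sl_flag == 1 and r.cl_flag == 1
        assert r.lrt_statistic >= 0
        assert r.p_value < 0.01

    def test_nineteen_lof_patients_inapplicable(self):
        rng = np.random.default_rng(1)
        n = 200
        ga = np.zeros(n, dtype=int)
        ga[:19] = 1
        gb = rng.integers(0, 2, n)
        t, e = draw_survival(rng, np.zeros(n), 0.02, 0.0)
        r = survlrt(ga, gb, t, e, self.ref)
        assert not r.applicable and "19 < 20" in r.reason

    def test_sparse_genotype_group_inapplicable(self):
        deltas = {g: 0.0 for g in [(0, 0), (0, 1), (1, 0), (1, 1)]}
        ga, gb, t, e = make_genotype_data(2, deltas, n_per_group=50, censoring=0.0)
        # wipe events in genotype (1,1) below the gate
        mask = (ga == 1) & (gb == 1)
        e = e.copy()
        e[np.flatnonzero(mask)[4:]] = 0
        r = survlrt(ga, gb, t, e, self.ref)
        assert not r.applicable and "(1, 1)" in r.reason

    def test_wild_type_gate_can_be_exempted(self):
        deltas = {g: 0.0 for g in [(0, 0), (0, 1), (1, 0), (1, 1)]}
        ga, gb, t, e = make_genotype_data(3, deltas, n_per_group=50, censoring=0.0)
        mask = (ga == 0) & (gb == 0)
        e = e.copy()
        e[np.flatnonzero(mask)[4:]] = 0  # 4 deceased in (0,0): gate fails
        assert not survlrt(ga, gb, t, e, self.ref).applicable
        r = survlrt(ga, gb, t, e, self.ref, gate_wild_type_group=False)
        assert r.applicable

    def test_lrt_statistic_non_negative_over_random_draws(self):
        deltas = {(0, 0): 0.0, (0, 1): -0.4, (1, 0): -0.1, (1, 1): -0.5}  # null
        for seed in range(10):
            ga, gb, t, e = make_genotype_data(seed, deltas, n_per_group=60)
            r = survlrt(ga, gb, t, e, self.ref)
            if r.applicable:
                assert r.lrt_statistic >= 0.0


class TestISurvLRT:
    ref = exponential_reference(0.02, t_max=5000, n_steps=50000)

    def make_expression_data(self, seed=0, n=600):
        rng = np.random.default_rng(seed)
        ga = (rng.random(n) < 0.3).astype(int)
        expr = rng.normal(size=n)
        gb = (expr < np.quantile(expr, 0.25)).astype(int)
        deltas = {(0, 0): 0.0, (0, 1): -0.2, (1, 0): -0.2, (1, 1): -1.5}
        lf = np.array([deltas[(a, b)] for a, b in zip(ga, gb)])
        t, e = draw_survival(rng, lf, 0.02, 0.2)
        return ga, expr, t, e

    def test_returned_p_is_minimum_over_thresholds(self):
        ga, expr, t, e = self.make_expression_data()
        r = isurvlrt(ga, expr, t, e, self.ref)
        assert r.applicable
        # direct recomputation oracle over the full grid
        for q in np.arange(0.05, 0.501, 0.05):
            gb = (expr < np.quantile(expr, q)).astype(int)
            it = survlrt(ga, gb, t, e, self.ref, min_lof=None)
            if it.applicable:
                assert r.p_value <= it.p_value + 1e-12

    def test_nineteen_lof_patients_inapplicable(self):
        rng = np.random.default_rng(4)
        n = 100
        ga = np.zeros(n, dtype=int)
        ga[:19] = 1
        t, e = draw_survival(rng, np.zeros(n), 0.02, 0.0)
        r = isurvlrt(ga, rng.normal(size=n), t, e, self.ref)
        assert not r.applicable and "19 < 20" in r.reason

    def test_constant_expression_collapses_to_no_iteration(self):
        rng = np.random.default_rng(5)
        n = 200
        ga = (rng.random(n) < 0.4).astype(int)
        t, e = draw_survival(rng, np.zeros(n), 0.02, 0.0)
        r = isurvlrt(ga, np.full(n, 3.0), t, e, self.ref)
        # e_B < t is false everywhere at the single deduplicated threshold
        assert not r.applicable
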