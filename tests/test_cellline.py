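"""Cell-line test checks against independent enumeration and walk oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slidekit.cellline import (
    positive_dependency_percentage,
    run_cellline_tests,
    spea_es,
    spea_pvalue,
    spid,
)
from slidekit.datatypes import AlterationMatrix, DependencyScreen, GenePair
import pandas as pd


def exact_ranksum_p_less(x, y):
    """Oracle: enumerate every assignment of the pooled values into two
    groups; one-sided P(rank sum of group 1 <= observed)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0  # tie-free inputs only
    n1 = len(x)
    observed = ranks[:n1].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(idx)].sum() <= observed:
            count += 1
    return count / total


class TestSpid:
    def test_most_extreme_arrangement(self):
        r = spid([-3, -2.5, -2, 0, 0.5, 1], [1, 1, 1, 0, 0, 0])
        assert r.p_value == pytest.approx(1 / 20)
        assert r.direction_sl

    def test_opposite_direction_has_large_p(self):
        r = spid([0, 0.5, 1, -3, -2.5, -2], [1, 1, 1, 0, 0, 0])
        assert r.p_value >= 0.95
        assert not r.direction_sl

    def test_no_separation_has_p_at_least_half(self):
        r = spid([0.3, -0.1, 0.2, -0.2, 0.1, -0.3], [1, 0, 1, 0, 1, 0])
        assert r.p_value >= 0.4

    @pytest.mark.parametrize("n1,n2,seed", [(3, 5, 0), (5, 5, 1), (8, 8, 2), (2, 7, 3)])
    def test_matches_exact_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n1 + n2)
        lof = np.array([1] * n1 + [0] * n2)
        r = spid(scores, lof)
        assert r.p_value == pytest.approx(
            exact_ranksum_p_less(scores[:n1], scores[n1:])
        )

    def test_missing_scores_dropped_and_empty_group_inapplicable(self):
        r = spid([np.nan, np.nan, 1.0, 2.0], [1, 1, 0, 0])
        assert not r.applicable and np.isnan(r.p_value)


@pytest.mark.parametrize(
    "scores,lof,expected",
    [([0.5, 1.2], [1, 1], 1.0), ([-1, -2, -3], [1, 1, 1], 0.0), ([-1, 2], [1, 1], 0.5)],
)
def test_positive_dependency_percentage(scores, lof, expected):
    assert positive_dependency_percentage(scores, lof) == expected


def test_positive_dependency_all_lines_denominator():
    assert positive_dependency_percentage([2.0, -1.0, -3.0, 4.0], [1, 0, 1, 0],
                                          denominator="all") == 0.25


def walk_oracle(scores, lof, w_exp):
    """Independent step-by-step running-sum recomputation."""
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    hits = [bool(lof[i]) for i in order]
    weights = [abs(scores[i]) ** w_exp for i in order]
    hit_total = sum(w for w, h in zip(weights, hits) if h)
    n_miss = hits.count(False)
    running, best = 0.0, 0.0
    for h, w in zip(hits, weights):
        running += w / hit_total if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestSpeaEs:
    def test_single_lof_first_is_plus_one(self):
        assert spea_es([-3, -1, 0, 1], [1, 0, 0, 0]) == pytest.approx(1.0)

    def test_single_lof_last_is_minus_one(self):
        assert spea_es([-3, -1, 0, 1], [0, 0, 0, 1]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("w_exp", [0.0, 1.0, 2.0])
    def test_matches_walk_oracle(self, seed, w_exp):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=12)
        lof = rng.random(12) < 0.3
        if lof.sum() in (0, 12):
            lof[0] = ~lof[0]
        es = spea_es(scores, lof.astype(int), weight_exponent=w_exp)
        assert es == pytest.approx(walk_oracle(scores, lof, w_exp))
        assert -1.0 <= es <= 1.0

    def test_two_lof_of_six_hand_case(self):
        scores = [-3, -2, -1, 1, 2, 3]
        lof = [1, 1, 0, 0, 0, 0]
        assert spea_es(scores, lof) == pytest.approx(walk_oracle(scores, lof, 1.0))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        scores=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=4,
            max_size=20,
        ),
        data=st.data(),
    )
    def test_es_bounded_for_arbitrary_inputs(self, scores, data):
        n = len(scores)
        lof = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < n
            )
        )
        es = spea_es(np.array(scores), np.array(lof))
        assert -1.0 - 1e-9 <= es <= 1.0 + 1e-9

    def test_all_zero_scores_fall_back_to_unweighted(self, caplog):
        with caplog.at_level("WARNING"):
            es = spea_es([0, 0, 0, 0], [1, 0, 0, 0])
        assert "unweighted" in caplog.text
        assert es == pytest.approx(1.0)


class TestSpeaPvalue:
    def test_floor_at_200_permutations(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(-3, 0.5, 25), rng.normal(0, 0.5, 75)])
        lof = np.array([1] * 25 + [0] * 75)
        r = spea_pvalue(scores, lof, n_perm=200, seed=1)
        assert r.p_value == pytest.approx(1 / 201)
        assert round(r.p_value, 3) == 0.005

    def test_p_never_below_floor_and_seed_reproducible(self, rng):
        scores = rng.normal(size=40)
        lof = (rng.random(40) < 0.3).astype(int)
        r1 = spea_pvalue(scores, lof, n_perm=99, seed=5)
        r2 = spea_pvalue(scores, lof, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value  # bit-identical under a fixed seed
        assert r1.p_value >= 1 / 100

    def test_single_permutation_p_is_half_or_one(self, rng):
        scores = rng.normal(size=10)
        lof = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        p = spea_pvalue(scores, lof, n_perm=1, seed=3).p_value
        assert p in (0.5, 1.0)


class TestGates:
    def make_inputs(self, n_lof):
        lines = [f"c{i}" for i in range(60)]
        rng = np.random.default_rng(0)
        screen = DependencyScreen(
            "s1",
            pd.DataFrame(rng.normal(size=(60, 2)), index=lines, columns=["A", "B"]),
        )
        lof = np.zeros(60, dtype=int)
        lof[:n_lof] = 1
        alt = AlterationMatrix(
            pd.DataFrame({"A": lof, "B": np.zeros(60, dtype=int)}, index=lines)
        )
        return screen, alt

    def test_nineteen_lof_lines_inapplicable(self):
        screen, alt = self.make_inputs(19)
        results = run_cellline_tests(screen, alt, [GenePair("A", "B")], n_perm=10)
        assert all(not r.applicable for r in results)
        assert "19 < 20" in results[0].reason

    def test_twenty_lof_lines_applicable(self):
        screen, alt = self.make_inputs(20)
        results = run_cellline_tests(screen, alt, [GenePair("A", "B")], n_perm=10)
        assert all(r.applicable for r in results)

    def test_gene_b_not_a_target_inapplicable(self):
        screen, alt = self.make_inputs(30)
        results = run_cellline_tests(screen, alt, [GenePair("A", "ZZ")], n_perm=10)
        assert all(not r.applicable for r in results)
        assert "not a screen target" in results[0].reason
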