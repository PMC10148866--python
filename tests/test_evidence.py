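import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slidekit.evidence import (
    PipelineConfig,
    applicability,
    bh_adjust,
    evaluate_evidence,
    export_network,
    fisher_combine,
)
from slidekit.datatypes import GenePair


def chi2_even_df_sf(x, k):
    """Upper tail of chi-square with 2k df, independent closed form:
    exp(-x/2) * sum_{j<k} (x/2)^j / j!"""
    return math.exp(-x / 2) * sum((x / 2) ** j / math.factorial(j) for j in range(k))


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_is_identity(self):
        assert fisher_combine([0.037]) == pytest.approx(0.037)

    def test_four_halves_closed_form(self):
        stat = -2 * 4 * math.log(0.5)
        assert fisher_combine([0.5] * 4) == pytest.approx(chi2_even_df_sf(stat, 4))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form_random(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(4)
        stat = -2 * np.log(p).sum()
        assert fisher_combine(p) == pytest.approx(chi2_even_df_sf(stat, 4))

    def test_monotone_in_each_input(self, rng):
        p = rng.random(4)
        base = fisher_combine(p)
        for i in range(4):
            q = p.copy()
            q[i] *= 0.5
            assert fisher_combine(q) <= base

    def test_zero_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = fisher_combine([0.0, 0.5])
        assert 0 < out < 1 and "clamped" in caplog.text


def bh_oracle(p):
    """Independently coded textbook step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equally_spaced_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    @pytest.mark.parametrize("n", [2, 17, 1000])
    def test_matches_textbook_oracle(self, n, rng):
        p = rng.random(n)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_properties_hold_for_arbitrary_p_vectors(self, p):
        adj = bh_adjust(p)
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(p) - 1e-12).all()
        # order of adjusted values follows order of raw values
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        np.testing.assert_allclose(adj, bh_oracle(p))

    def test_adjusted_at_least_raw_and_nan_passthrough(self, rng):
        p = rng.random(50)
        p[::7] = np.nan
        adj = bh_adjust(p)
        mask = ~np.isnan(p)
        assert (adj[mask] >= p[mask] - 1e-15).all()
        assert np.isnan(adj[~mask]).all()


class TestEvaluateEvidence:
    cfg = PipelineConfig()

    def test_exprsl_needs_correlation_above_threshold(self):
        rec = {"exprsl_p_adj": 0.01, "exprsl_rho": 0.35, "combined_p_adj": np.nan}
        assert evaluate_evidence(dict(rec), self.cfg)["exprsl_evidence"] is False
        rec["exprsl_rho"] = 0.45
        assert evaluate_evidence(dict(rec), self.cfg)["exprsl_evidence"] is True

    def test_survlrt_needs_both_flags(self):
        rec = {
            "survlrt_p_adj": 0.01,
            "survlrt_sl_flag": 1,
            "survlrt_cl_flag": -1,
            "combined_p_adj": np.nan,
        }
        assert evaluate_evidence(dict(rec), self.cfg)["survlrt_evidence"] is False
        rec["survlrt_cl_flag"] = 1
        assert evaluate_evidence(dict(rec), self.cfg)["survlrt_evidence"] is True

    def test_clinical_relevance_requires_top_cellline_and_patient_evidence(self):
        rec = {"combined_p_adj": 0.01, "sof_p_adj": 0.01}
        out = evaluate_evidence(dict(rec), self.cfg)
        assert out["top_cellline"] is True and out["clinically_relevant"] is True
        rec = {"combined_p_adj": 0.01, "sof_p_adj": 0.8}
        assert not evaluate_evidence(dict(rec), self.cfg)["clinically_relevant"]
        rec = {"combined_p_adj": 0.2, "sof_p_adj": 0.01}
        assert not evaluate_evidence(dict(rec), self.cfg)["clinically_relevant"]

    def test_missing_modality_is_not_assessed_never_false(self):
        out = evaluate_evidence({"combined_p_adj": 0.01}, self.cfg)
        assert out["sof_evidence"] is None
        assert out["survlrt_evidence"] is None

    def test_spdd_uses_raw_p_by_default(self):
        rec = {"combined_p_adj": np.nan, "spdd_screen1_p": 0.03, "spdd_screen1_p_adj": 0.4}
        assert evaluate_evidence(dict(rec), self.cfg)["spdd_screen1_evidence"] is True
        cfg2 = PipelineConfig(spdd_use_adjusted=True)
        assert evaluate_evidence(dict(rec), cfg2)["spdd_screen1_evidence"] is False


class TestApplicability:
    def test_gates_on_small_bundle(self, small_bundle):
        b = small_bundle.bundle
        planted = GenePair("FA01", "FB01")
        assert applicability("SPID", planted, b)[0]
        assert applicability("SPSP", planted, b)[0]
        ok, reason = applicability("SPID", GenePair("FA01", "NOPE"), b)
        assert not ok and "screen target" in reason
        ok, reason = applicability("SPSP", GenePair("FA01", "NOPE"), b)
        assert not ok


class TestExportNetwork:
    def make_records(self):
        return pd.DataFrame(
            {
                "gene_a": ["A", "A", "B"],
                "gene_b": ["X", "Y", "Z"],
                "rank": [1, 2, 3],
                "spsp_shared": [3, 0, 1],
                "n_patient_evidence": [2, 1, 3],
                "spdd_screen1_p": [0.01, 0.5, np.nan],
                "spdd_screen1_drug": ["drugA", "drugB", ""],
            }
        )

    def test_nodes_edges_and_attributes(self):
        g = export_network(self.make_records(), top_n=3)
        assert g.nodes["A"]["partner_count"] == 2
        assert g.edges["A", "X"]["style"] == "solid"  # >=2 patient tests
        assert g.edges["A", "Y"]["style"] == "dashed"
        assert g.edges["A", "Y"]["weight"] == 0  # zero shared pathways kept
        assert g.edges["A", "X"]["best_drug"] == "drugA"
        assert g.edges["A", "Y"]["best_drug"] == ""  # p above threshold

    def test_top_n_exceeding_available_uses_all(self):
        g = export_network(self.make_records(), top_n=50)
        assert g.number_of_edges() == 3
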