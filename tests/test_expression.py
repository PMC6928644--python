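"""qPCR 2^-ddCt quantification, significance calls, and concordance."""

import numpy as np
import pandas as pd
import pytest

from fabpkit.datasets import agonist_response_table
from fabpkit.expression import (
    collapse_technical,
    concordance,
    delta_ct,
    expression_calls,
    fold_change_call,
    stage_profile,
)
from fabpkit.ppre_score import evaluate_elements
from fabpkit.synthetic_data import CtSimConfig, gen_ct_table


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


class TestCollapseTechnical:
    def test_triplicate_mean(self):
        ct = ct_frame([("s1", "c", "g", 20.0), ("s1", "c", "g", 20.2), ("s1", "c", "g", 20.1)])
        out = collapse_technical(ct)
        assert len(out) == 1
        assert out["ct"].iloc[0] == pytest.approx(20.1)

    def test_single_measurement_unchanged(self):
        ct = ct_frame([("s1", "c", "g", 22.5)])
        assert collapse_technical(ct)["ct"].iloc[0] == 22.5

    def test_spread_warning(self, caplog):
        ct = ct_frame([("s1", "c", "g", 20.0), ("s1", "c", "g", 20.0), ("s1", "c", "g", 26.0)])
        out = collapse_technical(ct)
        assert out["ct"].iloc[0] == pytest.approx(22.0)
        assert any("spread" in r.message for r in caplog.records)


class TestDeltaCt:
    def test_subtraction(self):
        ct = ct_frame([("s1", "c", "g", 25.0), ("s1", "c", "beta_actin", 20.0)])
        out = delta_ct(ct, "g")
        assert out["delta_ct"].iloc[0] == pytest.approx(5.0)

    def test_gene_equals_reference_gives_zero(self):
        ct = ct_frame([("s1", "c", "beta_actin", 20.0), ("s2", "c", "beta_actin", 21.0)])
        out = delta_ct(ct, "beta_actin")
        assert (out["delta_ct"] == 0.0).all()

    def test_sample_without_reference_dropped_with_warning(self, caplog):
        ct = ct_frame(
            [
                ("s1", "c", "g", 25.0),
                ("s1", "c", "beta_actin", 20.0),
                ("s2", "c", "g", 25.0),  # no reference row
            ]
        )
        out = delta_ct(ct, "g")
        assert list(out["sample_id"]) == ["s1"]
        assert any("dropped" in r.message for r in caplog.records)


class TestFoldChangeCall:
    def test_null_case_fold_one_unchanged(self):
        dct = np.array([5.0, 5.2, 4.8, 5.1])
        call = fold_change_call(dct, dct)
        assert call.fold_change == pytest.approx(1.0)
        assert call.call == "unchanged"
        assert call.p_value == 1.0

    def test_ddct_minus_one_fold_two(self):
        call = fold_change_call([4.0, 4.0, 4.0], [5.0, 5.0, 5.0])
        assert call.fold_change == pytest.approx(2.0)
        assert call.delta_delta_ct == pytest.approx(-1.0)

    def test_zero_variance_equal_means_p_one(self):
        call = fold_change_call([5.0, 5.0], [5.0, 5.0])
        assert (call.p_value, call.call) == (1.0, "unchanged")

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            fold_change_call([5.0], [5.0, 5.1])

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        treat, control = rng.normal(4, 0.3, 8), rng.normal(5, 0.3, 8)
        fwd = fold_change_call(treat, control)
        rev = fold_change_call(control, treat)
        assert fwd.fold_change * rev.fold_change == pytest.approx(1.0)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_monte_carlo_recovery_planted_effect(self):
        """Planted ddCt = -2, sd 0.2, n 8: estimated fold in [3.4, 4.7] and
        called up in >= 95% of 200 seeded replicates."""
        ok_fold = ok_call = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            control = rng.normal(5.0, 0.2, 8)
            treat = rng.normal(3.0, 0.2, 8)
            call = fold_change_call(treat, control)
            ok_fold += 3.4 <= call.fold_change <= 4.7
            ok_call += call.call == "up"
        assert ok_call >= 0.95 * n_rep
        assert ok_fold >= 0.95 * n_rep


class TestReferenceNormalisationInvariance:
    def test_global_ct_shift_leaves_calls_unchanged(self):
        cfg = CtSimConfig(genes={"g1": 1.0, "g2": 0.0}, n_control=4, n_treatment=4, seed=8)
        ct = gen_ct_table(cfg)
        shifted = ct.copy()
        # add a per-sample efficiency shift to every Ct of that sample
        offsets = {s: i * 0.7 for i, s in enumerate(shifted["sample_id"].unique())}
        shifted["ct"] = shifted["ct"] + shifted["sample_id"].map(offsets)
        base = expression_calls(ct, "treatment", "control")
        moved = expression_calls(shifted, "treatment", "control")
        for b, m in zip(base, moved):
            assert b.delta_delta_ct == pytest.approx(m.delta_delta_ct)
            assert b.call == m.call


class TestStageProfile:
    def test_single_call_single_row(self):
        call = fold_change_call([4.0, 4.1], [5.0, 5.1], gene="g1")
        table = stage_profile([call])
        assert list(table["gene"]) == ["g1"]

    def test_duplicate_gene_error(self):
        call = fold_change_call([4.0, 4.1], [5.0, 5.1], gene="g1")
        with pytest.raises(ValueError, match="one call per gene"):
            stage_profile([call, call])

    def test_planted_pattern_recovered(self):
        pattern = {"g_up": 1.5, "g_down": -1.5, "g_null": 0.0}
        ct = gen_ct_table(CtSimConfig(genes=pattern, seed=21))
        calls = expression_calls(ct, "treatment", "control")
        profile = stage_profile(calls).set_index("gene")["call"]
        assert profile["g_up"] == "up"
        assert profile["g_down"] == "down"
        assert profile["g_null"] == "unchanged"


class TestConcordance:
    @staticmethod
    def _evals():
        return [
            evaluate_elements("FABP7", "AAACT", "AATTCTGAAAATA"),   # gamma
            evaluate_elements("FABP4", "AGAAC", "GGGCCAAACTTCA"),   # alpha
            evaluate_elements("FABP1", "GAAGT", "GGACTATGGATTA"),   # alpha
        ]

    def test_gamma_prediction_with_gamma_response_concordant(self):
        responses = pd.DataFrame(
            [
                ("FABP7", "PPARa", 100.0, "unchanged"),
                ("FABP7", "PPARb", 100.0, "unchanged"),
                ("FABP7", "PPARg", 100.0, "up"),
            ],
            columns=["gene", "agonist", "concentration", "call"],
        )
        report = concordance(self._evals()[:1], responses)
        assert report.table["concordant"].iloc[0] == True  # noqa: E712

    def test_prediction_without_response_discordant(self):
        responses = pd.DataFrame(
            [("FABP4", a, 100.0, "unchanged") for a in ("PPARa", "PPARb", "PPARg")],
            columns=["gene", "agonist", "concentration", "call"],
        )
        report = concordance([self._evals()[1]], responses)
        assert report.table["concordant"].iloc[0] == False  # noqa: E712

    def test_empty_response_table_reports_predictions_only(self):
        report = concordance(self._evals(), pd.DataFrame())
        assert len(report.table) == 3
        assert report.table["concordant"].isna().all()
        assert report.missing_responses == ["FABP1", "FABP4", "FABP7"]

    def test_shipped_reference_responses(self):
        """On the shipped agonist-response calls, the gamma-selective FABP7
        prediction is concordant and the alpha-selective FABP4 prediction
        (no response to any agonist) is discordant."""
        report = concordance(self._evals(), agonist_response_table())
        table = report.table.set_index("gene")
        assert table.loc["FABP7", "concordant"] == True  # noqa: E712
        assert table.loc["FABP4", "concordant"] == False  # noqa: E712


def test_null_generator_false_positive_rate_near_alpha():
    """Under the null, the significant-call fraction across replicates stays
    within binomial error of alpha."""
    n_rep, alpha = 120, 0.05
    significant = 0
    for rep in range(n_rep):
        ct = gen_ct_table(
            CtSimConfig(genes={"g": 0.0}, n_control=6, n_treatment=6, seed=40_000 + rep)
        )
        (call,) = expression_calls(ct, "treatment", "control")
        significant += call.call != "unchanged"
    # exact binomial 95% band for 120 trials at p = 0.05
    from scipy.stats import binom

    lo, hi = binom.ppf(0.025, n_rep, alpha), binom.ppf(0.975, n_rep, alpha)
    assert lo <= significant <= hi


def test_bh_adjustment_is_conservative():
    ct = gen_ct_table(
        CtSimConfig(genes={"g1": 1.5, "g2": 0.0, "g3": 0.2, "g4": 0.0}, seed=33)
    )
    raw = expression_calls(ct, "treatment", "control")
    adj = expression_calls(ct, "treatment", "control", p_adjust="bh")
    for r, a in zip(raw, adj):
        assert a.p_value >= r.p_value - 1e-15
        if r.call == "unchanged":
            assert a.call == "unchanged"  # correction never creates significance
    # a strong planted effect survives correction
    assert {a.gene: a.call for a in adj}["g1"] == "up"
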