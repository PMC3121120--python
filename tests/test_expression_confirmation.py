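"""Rule-based link confirmation: the rule table, counting, and tiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reglinkmap.expression_confirmation import (
    ConfirmationCounts,
    Outcome,
    RatioTier,
    TierConfig,
    assign_tier,
    classify_experiment,
    confirm_links,
    count_link,
)
from reglinkmap.io_formats import ExpressionCall, ExpressionMatrix, Sign
from reglinkmap.link_integration import PredictedLink

Y, N, AB = ExpressionCall.EXPRESSED, ExpressionCall.NOT_EXPRESSED, ExpressionCall.ABSENT
POS, NEG = Sign.POSITIVE, Sign.NEGATIVE

# Hand-enumerated rule table: activation confirms on co-expression,
# repression confirms on discordance; any absent call is uninformative.
RULE_TABLE = {
    (POS, Y, Y): Outcome.CONFIRMING,
    (POS, Y, N): Outcome.CONTRADICTORY,
    (POS, N, Y): Outcome.NEUTRAL,
    (POS, N, N): Outcome.IGNORED,
    (NEG, Y, Y): Outcome.CONTRADICTORY,
    (NEG, Y, N): Outcome.CONFIRMING,
    (NEG, N, Y): Outcome.CONFIRMING,
    (NEG, N, N): Outcome.CONTRADICTORY,
}


def make_link(sign=POS, tf="TF", tg="TG"):
    return PredictedLink("sTF", "sTG", tf, tg, sign, frozenset({"m"}), "TFsf-TGblbs")


def matrix(tf_calls, tg_calls, tf="TF", tg="TG"):
    exps = [f"e{i}" for i in range(len(tf_calls))]
    return ExpressionMatrix(
        pd.DataFrame([tf_calls, tg_calls], index=[tf, tg], columns=exps, dtype=object)
    )


class TestClassifyExperiment:
    @pytest.mark.parametrize("sign,tf_call,tg_call", list(RULE_TABLE))
    def test_rule_table(self, sign, tf_call, tg_call):
        assert classify_experiment(sign, tf_call, tg_call) == RULE_TABLE[
            (sign, tf_call, tg_call)
        ]

    @pytest.mark.parametrize("sign", [POS, NEG])
    @pytest.mark.parametrize("tf_call", [Y, N, AB])
    @pytest.mark.parametrize("tg_call", [Y, N, AB])
    def test_all_18_combinations_are_total_and_absent_ignores(self, sign, tf_call, tg_call):
        outcome = classify_experiment(sign, tf_call, tg_call)
        if AB in (tf_call, tg_call):
            assert outcome is Outcome.IGNORED
        else:
            assert outcome == RULE_TABLE[(sign, tf_call, tg_call)]

    def test_sign_flip_symmetry(self):
        """Flipping the sign swaps Confirming and Contradictory for the
        co-expressed and TF-only-expressed call patterns."""
        swap = {Outcome.CONFIRMING: Outcome.CONTRADICTORY,
                Outcome.CONTRADICTORY: Outcome.CONFIRMING}
        for calls in [(Y, Y), (Y, N)]:
            assert classify_experiment(NEG, *calls) == swap[
                classify_experiment(POS, *calls)
            ]


class TestCountLink:
    def test_unknown_genes_are_absent_everywhere(self):
        m = matrix([Y] * 43, [Y] * 43, tf="other1", tg="other2")
        counts = count_link(make_link(), m)
        assert counts == ConfirmationCounts(0, 0, 0, 43)

    def test_direct_enumeration(self):
        # both expressed in 5 of 8 experiments, TF-only in the remaining 3
        tf_calls = [Y] * 8
        tg_calls = [Y] * 5 + [N] * 3
        counts = count_link(make_link(POS), matrix(tf_calls, tg_calls))
        assert (counts.c, counts.contradictory) == (5, 3)
        assert counts.neutral == 0 and counts.ignored == 0

    def test_id_map_resolves_expression_genes(self):
        m = matrix([Y, Y], [Y, N], tf="gene_a", tg="gene_b")
        counts = count_link(
            make_link(POS), m, id_map={"TF": "gene_a", "TG": "gene_b"}
        )
        assert (counts.c, counts.contradictory) == (1, 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_sum_to_experiment_count(self, seed):
        rng = np.random.default_rng(seed)
        calls = [Y, N, AB]
        tf_calls = [calls[i] for i in rng.integers(3, size=20)]
        tg_calls = [calls[i] for i in rng.integers(3, size=20)]
        for sign in (POS, NEG):
            counts = count_link(make_link(sign), matrix(tf_calls, tg_calls))
            assert counts.n_experiments == 20


def oracle_tier(c, x, n):
    """Independent case analysis of the default tier boundaries."""
    if c == x == n == 0:
        return RatioTier.NO_DATA
    if x > c:
        return RatioTier.UNSUPPORTED
    if c >= 3 * x:
        return RatioTier.STRONG_3X
    if c >= 2 * x:
        return RatioTier.STRONG_2X
    return RatioTier.WEAK


class TestAssignTier:
    def test_verified_and_strong(self):
        grade = assign_tier(ConfirmationCounts(5, 1, 2, 0))
        assert grade.verified  # 5 > 2*1 + 1*2
        assert grade.ratio_tier is RatioTier.STRONG_3X  # 5 >= 3

    def test_unsupported_not_verified(self):
        grade = assign_tier(ConfirmationCounts(0, 1, 0, 10))
        assert not grade.verified
        assert grade.ratio_tier is RatioTier.UNSUPPORTED

    def test_no_informative_experiments(self):
        grade = assign_tier(ConfirmationCounts(0, 0, 0, 43))
        assert grade.ratio_tier is RatioTier.NO_DATA

    def test_verified_boundary_is_strict(self):
        # c exactly equal to the weighted sum is NOT verified
        assert not assign_tier(ConfirmationCounts(4, 1, 2, 0)).verified
        assert assign_tier(ConfirmationCounts(5, 1, 2, 0)).verified

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_partition_matches_case_analysis(self, c, x, n):
        grade = assign_tier(ConfirmationCounts(c, x, n, 0))
        assert grade.ratio_tier is oracle_tier(c, x, n)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_increasing_c_never_demotes(self, c, x, n):
        order = [RatioTier.UNSUPPORTED, RatioTier.WEAK, RatioTier.STRONG_2X,
                 RatioTier.STRONG_3X]
        before = assign_tier(ConfirmationCounts(c, x, n, 0))
        after = assign_tier(ConfirmationCounts(c + 1, x, n, 0))
        assert after.verified or not before.verified
        if before.ratio_tier is not RatioTier.NO_DATA:
            assert order.index(after.ratio_tier) >= order.index(before.ratio_tier)

    def test_custom_boundaries(self):
        config = TierConfig(ratio_high=4, ratio_mid=2)
        assert assign_tier(
            ConfirmationCounts(6, 2, 0, 0), config
        ).ratio_tier is RatioTier.STRONG_2X


class TestConfirmLinks:
    def test_all_links_no_data(self):
        m = matrix([AB, AB], [AB, AB])
        report = confirm_links([make_link(), make_link(tg="TG2")], m)
        assert report.n_analyzed == 0

    def test_tier_totals_partition_analyzed_links(self):
        rng = np.random.default_rng(7)
        calls = [Y, N, AB]
        genes = [f"g{i}" for i in range(12)]
        frame = pd.DataFrame(
            [[calls[i] for i in rng.integers(3, size=15)] for _ in genes],
            index=genes, columns=[f"e{i}" for i in range(15)], dtype=object,
        )
        m = ExpressionMatrix(frame)
        links = [
            make_link(POS if i % 2 else NEG, tf=genes[i], tg=genes[-1 - i])
            for i in range(6)
        ]
        report = confirm_links(links, m)
        assert sum(report.tier_totals.values()) == report.n_analyzed
        assert report.n_links == 6

    def test_true_links_verify_more_often_than_decoys(self, tiny_identity_scenario):
        """With Confirming planted at 0.8 for true links and coin-flip
        expression for decoys, the verified rate separates them."""
        scenario = tiny_identity_scenario
        true_links = [
            make_link(sign, tf=tf, tg=tg)
            for tf, tg, sign in sorted(
                scenario.truth.conserved_links, key=lambda x: (x[0], x[1])
            )
        ]
        decoys = [
            make_link(POS, tf=tf, tg=f"DEC{i % 4:03d}")
            for i, (tf, _, _) in enumerate(sorted(scenario.truth.conserved_links))
        ]
        report_true = confirm_links(true_links, scenario.expression)
        report_decoy = confirm_links(decoys, scenario.expression)
        rate_true = report_true.n_verified / report_true.n_links
        rate_decoy = report_decoy.n_verified / max(report_decoy.n_links, 1)
        assert rate_true > rate_decoy
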