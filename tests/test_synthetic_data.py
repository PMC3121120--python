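"""Scenario generator: primitives, construction guarantees, calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from reglinkmap.expression_confirmation import count_link
from reglinkmap.io_formats import MotifDefinition, SequenceRecord, Sign
from reglinkmap.link_integration import PredictedLink
from reglinkmap.motif_scan import contains_any, scan_sequence
from reglinkmap.synthetic_data import (
    ScenarioParams,
    generate_scenario,
    mutate_sequence,
    plant_motif,
)

from conftest import tiny_params


class TestMutateSequence:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 25
        assert mutate_sequence(seq, 0.0, rng) == seq

    def test_rate_one_changes_every_base(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 25
        mutated = mutate_sequence(seq, 1.0, rng)
        assert all(a != b for a, b in zip(seq, mutated))

    def test_substitution_fraction_within_binomial_bounds(self):
        rng = np.random.default_rng(42)
        n, rate = 10_000, 0.1
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=n))
        mutated = mutate_sequence(seq, rate, rng)
        observed = sum(a != b for a, b in zip(seq, mutated)) / n
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) <= 3 * se


class TestPlantMotif:
    def test_plant_then_scan_finds_the_occurrence(self):
        rng = np.random.default_rng(1)
        seq = "A" * 40
        motif = MotifDefinition("TF", "m", "TGASTC")
        planted = plant_motif(seq, motif.consensus, 10, rng)
        occs = scan_sequence(motif, SequenceRecord("s", planted), "forward")
        assert any(o.start == 10 for o in occs)

    def test_all_n_motif_matches_any_realization(self):
        rng = np.random.default_rng(2)
        motif = MotifDefinition("TF", "m", "NNNN")
        planted = plant_motif("ACGTACGT", motif.consensus, 2, rng)
        assert len(planted) == 8
        assert scan_sequence(motif, SequenceRecord("s", planted), "forward")

    def test_out_of_range_position_is_an_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="plant"):
            plant_motif("ACGT", "TTTTT", 2, rng)

    def test_degenerate_positions_realized_uniformly(self):
        """1000 plants of an R (A/G) position: frequencies pass chi-square."""
        rng = np.random.default_rng(3)
        first = [plant_motif("CCCC", "R", 0, rng)[0] for _ in range(1000)]
        counts = [first.count("A"), first.count("G")]
        assert set(first) <= {"A", "G"}
        assert stats.chisquare(counts).pvalue > 1e-3


class TestGenerateScenario:
    def test_identity_scenario_targets_equal_source(self, tiny_identity_scenario):
        scenario = tiny_identity_scenario
        source = {r.id: r.residues for r in scenario.source_tfs + scenario.source_tgs}
        for src_id, tgt_id in (
            scenario.truth.tf_homolog_pairs | scenario.truth.tg_homolog_pairs
        ):
            target = next(r for r in scenario.target_seqs if r.id == tgt_id)
            assert target.residues == source[src_id]

    def test_zero_link_conservation_empties_the_truth(self):
        scenario = generate_scenario(tiny_params(frac_link_conserved=0.0, seed=5))
        assert scenario.truth.conserved_links == frozenset()

    def test_conserved_links_reference_conserved_elements(self, tiny_noisy_scenario):
        truth = tiny_noisy_scenario.truth
        tf_targets = {t for _, t in truth.tf_homolog_pairs}
        tg_targets = {t for _, t in truth.tg_homolog_pairs}
        for tf, tg, _ in truth.conserved_links:
            assert tf in tf_targets and tg in tg_targets

    def test_every_conserved_link_target_contains_a_regulator_motif(
        self, tiny_noisy_scenario
    ):
        scenario = tiny_noisy_scenario
        by_id = {r.id: r for r in scenario.target_seqs}
        source_tf_of = {f"T{l.tf_id}": l.tf_id for l in scenario.network}
        for tf, tg, _ in scenario.truth.conserved_links:
            motifs = [m for m in scenario.motifs if m.tf_id == source_tf_of[tf]]
            assert contains_any(by_id[tg], motifs)

    def test_impossible_parameters_rejected(self):
        with pytest.raises(ValueError, match="motif_len"):
            ScenarioParams(motif_len=100, seq_len_tg=50, promoter_len=50)
        with pytest.raises(ValueError, match="p_confirm"):
            ScenarioParams(p_confirm_true=0.8, p_contradict_true=0.5)

    def test_reproducible_and_byte_identical(self, tmp_path):
        params = tiny_params(seed=99)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_scenario(params).write(a)
        generate_scenario(params).write(b)
        files = sorted(p.name for p in a.iterdir())
        assert files == sorted(p.name for p in b.iterdir())
        for name in files:
            assert (a / name).read_bytes() == (b / name).read_bytes(), name


class TestExpressionCalibration:
    def test_confirming_rate_converges_to_planting_rate(self):
        """Activation links over many experiments: the empirical Confirming
        fraction matches p_confirm_true within 3 standard errors."""
        n_exp = 2000
        params = tiny_params(
            n_experiments=n_exp,
            p_absent=0.0,
            frac_tf_conserved=1.0,
            frac_tg_conserved=1.0,
            frac_link_conserved=1.0,
            frac_positive=1.0,
            seed=17,
        )
        scenario = generate_scenario(params)
        p = params.p_confirm_true
        se = math.sqrt(p * (1 - p) / n_exp)
        assert scenario.truth.conserved_links
        for tf, tg, sign in scenario.truth.conserved_links:
            link = PredictedLink("s", "s", tf, tg, sign, frozenset({"m"}), "TFsf-TGblbs")
            counts = count_link(link, scenario.expression)
            assert abs(counts.c / n_exp - p) <= 3 * se, (tf, tg)

    def test_contradictory_rate_also_calibrated(self):
        n_exp = 2000
        params = tiny_params(
            n_experiments=n_exp, p_absent=0.0, frac_tf_conserved=1.0,
            frac_tg_conserved=1.0, frac_link_conserved=1.0, frac_positive=1.0,
            p_confirm_true=0.6, p_contradict_true=0.2, seed=19,
        )
        scenario = generate_scenario(params)
        se = math.sqrt(0.2 * 0.8 / n_exp)
        tf, tg, sign = sorted(scenario.truth.conserved_links)[0]
        link = PredictedLink("s", "s", tf, tg, sign, frozenset({"m"}), "TFsf-TGblbs")
        counts = count_link(link, scenario.expression)
        assert abs(counts.contradictory / n_exp - 0.2) <= 3 * se
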