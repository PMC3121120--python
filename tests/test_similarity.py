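"""Local alignment: exact scores vs an independent enumeration oracle."""

import functools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reglinkmap.io_formats import SequenceRecord
from reglinkmap.similarity import (
    ScoringScheme,
    filter_hits,
    find_similar,
    local_align,
)
from reglinkmap.synthetic_data import mutate_sequence


def oracle_local_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Best local score by memoized enumeration of alignments starting at
    every (i, j), independent of the production aligner."""

    @functools.lru_cache(maxsize=None)
    def from_here(i: int, j: int) -> float:
        best = 0.0  # the empty extension is always allowed (local)
        if i < len(a) and j < len(b):
            step = match if a[i] == b[j] else mismatch
            best = max(best, step + from_here(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + from_here(i + 1, j))
        if j < len(b):
            best = max(best, gap + from_here(i, j + 1))
        return best

    return max(
        from_here(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1)
    )


def rec(seq_id: str, residues: str) -> SequenceRecord:
    return SequenceRecord(seq_id, residues)


class TestLocalAlign:
    def test_self_alignment_scores_length_times_match(self):
        r = local_align(rec("a", "ACGT"), rec("b", "ACGT"))
        assert r.score == 4.0
        assert r.identity_fraction == 1.0

    def test_disjoint_sequences_score_zero(self):
        r = local_align(rec("a", "AAAA"), rec("b", "CCCC"))
        assert r.score == 0.0
        assert r.identity_fraction == 0.0

    def test_alphabet_mismatch_is_an_error(self):
        prot = SequenceRecord("p", "MKV", alphabet="protein")
        with pytest.raises(ValueError, match="alphabet"):
            local_align(rec("a", "ACGT"), prot)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(1, 13)))
            b = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(1, 13)))
            assert local_align(rec("a", a), rec("b", b)).score == oracle_local_score(a, b)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_self_score_property(self, seq):
        assert local_align(rec("a", seq), rec("b", seq)).score == len(seq)

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=12),
        st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_score_is_symmetric(self, a, b):
        assert (
            local_align(rec("a", a), rec("b", b)).score
            == local_align(rec("b", b), rec("a", a)).score
        )

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=10),
        st.text(alphabet="ACGT", min_size=1, max_size=10),
        st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_appending_residues_never_decreases_score(self, a, b, extra):
        base = local_align(rec("a", a), rec("b", b)).score
        assert local_align(rec("a", a + extra), rec("b", b)).score >= base
        assert local_align(rec("a", a), rec("b", b + extra)).score >= base


class TestFindSimilar:
    def test_identical_pair_yields_one_hit(self):
        hits = find_similar([rec("q", "ACGTACGT")], [rec("s", "ACGTACGT")], min_score=8)
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0
        assert hits[0].evalue == pytest.approx(math.exp(-8.0))

    def test_unattainable_min_score_yields_nothing(self):
        assert find_similar([rec("q", "ACGT")], [rec("s", "ACGT")], min_score=100) == []

    def test_empty_query_set_is_not_an_error(self):
        assert find_similar([], [rec("s", "ACGT")], min_score=1) == []

    def test_planted_homologs_separate_from_background(self):
        rng = np.random.default_rng(42)
        length = 120
        sources = [
            rec(f"q{i}", "".join("ACGT"[x] for x in rng.integers(4, size=length)))
            for i in range(5)
        ]
        # subject i is a 5%-mutated copy of query i; score distributions of
        # planted vs background pairs are far apart at this length
        subjects = [
            rec(f"s{i}", mutate_sequence(q.residues, 0.05, rng))
            for i, q in enumerate(sources)
        ]
        planted_scores, background_scores = [], []
        for i, q in enumerate(sources):
            for j, s in enumerate(subjects):
                score = local_align(q, s).score
                (planted_scores if i == j else background_scores).append(score)
        threshold = (min(planted_scores) + max(background_scores)) / 2
        assert max(background_scores) < min(planted_scores)
        hits = find_similar(sources, subjects, min_score=threshold)
        assert {(h.query_id, h.subject_id) for h in hits} == {
            (f"q{i}", f"s{i}") for i in range(5)
        }


class TestFilterHits:
    def _hits(self, evalues):
        return find_similar(
            [rec("q", "ACGTACGTACGT")], [rec("s", "ACGTACGTACGT")], min_score=4
        ) if evalues is None else None

    def test_threshold_keeps_only_small_evalues(self):
        hits = find_similar([rec("q", "ACGTACGTACGT")], [rec("s", "ACGT")], min_score=2)
        strong = find_similar(
            [rec("q", "ACGTACGTACGT")], [rec("s", "ACGTACGTACGT")], min_score=2
        )
        both = hits + strong
        kept = filter_hits(both, math.exp(-10))
        assert kept == strong

    def test_infinite_threshold_is_identity(self):
        hits = find_similar([rec("q", "ACGTAC")], [rec("s", "ACGTAC")], min_score=2)
        assert filter_hits(hits, float("inf")) == hits

    def test_agrees_with_linear_scan(self):
        rng = np.random.default_rng(3)
        seqs = [
            rec(f"x{i}", "".join("ACGT"[x] for x in rng.integers(4, size=30)))
            for i in range(6)
        ]
        hits = find_similar(seqs[:3], seqs[3:], min_score=2)
        cutoff = math.exp(-6)
        assert filter_hits(hits, cutoff) == [h for h in hits if h.evalue <= cutoff]
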