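"""Sequence-similarity search at desk scale.

The pipeline needs similarity hits between source-genome query sequences and
the target-genome database.  Users with real genomes bring precomputed hit
tables (``io_formats.read_similarity_table``); for everything else this module
computes optimal local alignments (match/mismatch scoring, linear gap penalty)
via :class:`Bio.Align.PairwiseAligner` and emits hits in the same tabular
dialect.

The e-value written by :func:`find_similar` is the monotone surrogate
``exp(-score)``.  It ranks hits consistently within one run but is not a
database-size-corrected statistic; downstream filtering by e-value therefore
behaves identically to filtering by score for internally computed hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .io_formats import Alphabet, SequenceRecord, SimilarityHit

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "local_align",
    "find_similar",
    "filter_hits",
    "DEFAULT_MAX_EVALUE",
]

#: Conventional stringent e-value cut-off applied when none is given.
DEFAULT_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/linear-gap scores for local alignment."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if self.gap >= 0:
            raise ValueError("gap score must be negative")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment between one query and one subject.

    Spans are 0-based half-open on the original sequences; an empty local
    alignment (score 0) has empty spans and identity 0.
    """

    query_id: str
    subject_id: str
    score: float
    q_span: tuple
    s_span: tuple
    identity_fraction: float
    alignment_length: int = 0
    n_identical: int = 0
    n_mismatches: int = 0
    n_gaps: int = 0


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap
    aligner.extend_gap_score = scheme.gap
    return aligner


def _empty_result(query: SequenceRecord, subject: SequenceRecord) -> AlignmentResult:
    return AlignmentResult(query.id, subject.id, 0.0, (0, 0), (0, 0), 0.0)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme = ScoringScheme(),
) -> AlignmentResult:
    """Optimal local alignment of two same-alphabet sequences.

    The score is the exact optimum under the scoring scheme.  Spans and
    identity come from the aligner's first reported optimal traceback, which
    is deterministic for fixed inputs.
    """
    if query.alphabet is not subject.alphabet:
        raise ValueError(
            f"alphabet mismatch: {query.id} is {query.alphabet.value}, "
            f"{subject.id} is {subject.alphabet.value}"
        )
    if not query.residues or not subject.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(scheme)
    score = float(aligner.score(query.residues, subject.residues))
    if score <= 0:
        return _empty_result(query, subject)
    alignment = next(iter(aligner.align(query.residues, subject.residues)))
    q_blocks, s_blocks = alignment.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return AlignmentResult(
        query_id=query.id,
        subject_id=subject.id,
        score=score,
        q_span=q_span,
        s_span=s_span,
        identity_fraction=counts.identities / length if length else 0.0,
        alignment_length=length,
        n_identical=counts.identities,
        n_mismatches=counts.mismatches,
        n_gaps=counts.gaps,
    )


def find_similar(
    queries: Sequence,
    subjects: Sequence,
    scheme: ScoringScheme = ScoringScheme(),
    min_score: float = 1.0,
) -> list:
    """All-vs-all local alignment, reporting pairs scoring >= ``min_score``.

    Results are ordered by (query_id, subject_id).  The ``evalue`` field of
    each hit is the surrogate ``exp(-score)`` (see module docstring).
    """
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    aligner = _make_aligner(scheme)
    hits: list = []
    for query in sorted(queries, key=lambda r: r.id):
        for subject in sorted(subjects, key=lambda r: r.id):
            if query.alphabet is not subject.alphabet:
                raise ValueError(
                    f"alphabet mismatch between {query.id} and {subject.id}"
                )
            score = float(aligner.score(query.residues, subject.residues))
            if score < min_score:
                continue
            result = local_align(query, subject, scheme)
            hits.append(
                SimilarityHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    percent_identity=100.0 * result.identity_fraction,
                    alignment_length=result.alignment_length,
                    mismatches=result.n_mismatches,
                    gap_opens=result.n_gaps,
                    q_start=result.q_span[0] + 1,
                    q_end=result.q_span[1],
                    s_start=result.s_span[0] + 1,
                    s_end=result.s_span[1],
                    evalue=math.exp(-score),
                    score=score,
                )
            )
    return hits


def filter_hits(hits: Iterable, max_evalue: float) -> list:
    """Keep hits with evalue <= ``max_evalue``, preserving input order."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be positive")
    return [h for h in hits if h.evalue <= max_evalue]
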