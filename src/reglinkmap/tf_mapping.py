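"""Transcription-factor mapping: similarity hits refined by family concordance.

Three nested result sets are produced for the target genome:

* ``TFbl`` — every target sequence similar to a source TF (similarity only);
* ``TFf``  — TFbl pairs where source and target share a protein family;
* ``TFsf`` — TFf pairs where they also share a protein subfamily.

Family/subfamily labels are inputs (e.g. exported from a PANTHER-style scan);
refinement is a concordance test on those labels, never a re-scan.  Pairs
where either side lacks the required label are dropped: refinement is a
positive evidence requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import AnnotationRecord
from .similarity import DEFAULT_MAX_EVALUE, filter_hits

__all__ = ["TFMappingSet", "map_tf_bl", "map_tf_family", "map_tf_subfamily"]

TF_LABELS = ("TFbl", "TFf", "TFsf")


@dataclass(frozen=True)
class TFMappingSet:
    """A set of (source TF, target sequence) pairs with its provenance label."""

    label: str
    pairs: frozenset  # of (source_tf_id, target_seq_id)

    def __post_init__(self) -> None:
        if self.label not in TF_LABELS:
            raise ValueError(f"unknown TF mapping label {self.label!r}")

    @property
    def distinct_targets(self) -> frozenset:
        return frozenset(target for _, target in self.pairs)

    def targets_of(self, source_tf_id: str) -> set:
        return {t for s, t in self.pairs if s == source_tf_id}

    def __len__(self) -> int:
        return len(self.pairs)


def _ids(sequences_or_ids: Iterable) -> set:
    return {getattr(item, "id", item) for item in sequences_or_ids}


def map_tf_bl(
    source_tfs: Iterable,
    hits: Iterable,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> TFMappingSet:
    """Similarity-only TF mapping: hit pairs surviving the e-value filter."""
    tf_ids = _ids(source_tfs)
    hits = list(hits)
    stray = {h.query_id for h in hits} - tf_ids
    if stray:
        raise ValueError(
            f"hit table queries are not source TFs: {sorted(stray)[:5]}"
        )
    kept = filter_hits(hits, max_evalue)
    return TFMappingSet("TFbl", frozenset((h.query_id, h.subject_id) for h in kept))


def _refine(
    pairs: frozenset,
    source_annot: Mapping,
    target_annot: Mapping,
    attr: str,
) -> frozenset:
    kept = set()
    for source_id, target_id in pairs:
        sa: AnnotationRecord | None = source_annot.get(source_id)
        ta: AnnotationRecord | None = target_annot.get(target_id)
        if sa is None or ta is None:
            continue
        s_label, t_label = getattr(sa, attr), getattr(ta, attr)
        if s_label is not None and s_label == t_label:
            kept.add((source_id, target_id))
    return frozenset(kept)


def map_tf_family(
    tfbl: TFMappingSet,
    source_annot: Mapping,
    target_annot: Mapping,
) -> TFMappingSet:
    """Keep TFbl pairs whose two sides carry the same protein family."""
    if tfbl.label != "TFbl":
        raise ValueError(f"expected a TFbl set, got {tfbl.label}")
    return TFMappingSet("TFf", _refine(tfbl.pairs, source_annot, target_annot, "family_id"))


def map_tf_subfamily(
    tff: TFMappingSet,
    source_annot: Mapping,
    target_annot: Mapping,
) -> TFMappingSet:
    """Keep TFf pairs whose two sides carry the same protein subfamily."""
    if tff.label != "TFf":
        raise ValueError(f"expected a TFf set, got {tff.label}")
    return TFMappingSet(
        "TFsf", _refine(tff.pairs, source_annot, target_annot, "subfamily_id")
    )
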