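"""Target-gene mapping: five result sets built from similarity and motifs.

* ``TGbl``   — target sequences similar to a source TG (similarity only);
* ``TGbs``   — target sequences containing >= 1 binding-site motif;
* ``TGblbs`` — TGbl pairs whose target also contains >= 1 motif of the
  source TG's regulating TF(s);
* ``TGpr``   — like TGbs but scanned over promoter sequences;
* ``TGgalf`` — like TGpr but with an externally discovered motif set.

TGbs/TGpr/TGgalf are one computation over different sequence databases and
motif provenances; they carry no source-gene association (``source_tg_id`` is
None) and are paired with source links only at integration time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import group_motifs
from .motif_scan import contains_any
from .similarity import DEFAULT_MAX_EVALUE, filter_hits

__all__ = [
    "TGMappingSet",
    "map_tg_bl",
    "map_tg_motif",
    "map_tg_bl_bs",
    "motifs_for_source_tgs",
]

logger = logging.getLogger(__name__)

TG_LABELS = ("TGbl", "TGbs", "TGblbs", "TGpr", "TGgalf")
MOTIF_ONLY_LABELS = ("TGbs", "TGpr", "TGgalf")


@dataclass(frozen=True)
class TGMappingSet:
    """Entries of (source_tg_id | None, target_seq_id, matched motif ids)."""

    label: str
    entries: frozenset  # of (source_tg_id or None, target_seq_id, frozenset[str])

    def __post_init__(self) -> None:
        if self.label not in TG_LABELS:
            raise ValueError(f"unknown TG mapping label {self.label!r}")
        for source_id, _, motif_ids in self.entries:
            if self.label in MOTIF_ONLY_LABELS and source_id is not None:
                raise ValueError(f"{self.label} entries must not carry a source TG")
            if self.label == "TGbl" and motif_ids:
                raise ValueError("TGbl entries carry no motifs")
            if self.label == "TGblbs" and not motif_ids:
                raise ValueError("TGblbs entries must carry matched motifs")

    @property
    def distinct_targets(self) -> frozenset:
        return frozenset(target for _, target, _ in self.entries)

    def targets_of(self, source_tg_id: str) -> set:
        """Target ids mapped from one source TG (similarity-based sets)."""
        return {t for s, t, _ in self.entries if s == source_tg_id}

    def __len__(self) -> int:
        return len(self.entries)


def _ids(sequences_or_ids: Iterable) -> set:
    return {getattr(item, "id", item) for item in sequences_or_ids}


def map_tg_bl(
    source_tgs: Iterable,
    hits: Iterable,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> TGMappingSet:
    """Similarity-only TG mapping: hit pairs surviving the e-value filter."""
    tg_ids = _ids(source_tgs)
    hits = list(hits)
    stray = {h.query_id for h in hits} - tg_ids
    if stray:
        raise ValueError(
            f"hit table queries are not source TGs: {sorted(stray)[:5]}"
        )
    kept = filter_hits(hits, max_evalue)
    return TGMappingSet(
        "TGbl",
        frozenset((h.query_id, h.subject_id, frozenset()) for h in kept),
    )


def map_tg_motif(
    target_seqs: Sequence,
    motifs: Sequence,
    strands: str = "both",
    label: str = "TGbs",
) -> TGMappingSet:
    """Motif-only TG mapping: every sequence containing >= 1 motif.

    ``label`` records the provenance: TGbs (gene sequences, known motifs),
    TGpr (promoters, known motifs) or TGgalf (promoters, externally
    discovered motifs).
    """
    if label not in MOTIF_ONLY_LABELS:
        raise ValueError(f"label must be one of {MOTIF_ONLY_LABELS}, got {label!r}")
    if not motifs:
        raise ValueError("motif set must be non-empty")
    entries = set()
    for seq in target_seqs:
        present = contains_any(seq, motifs, strands)
        if present:
            entries.add((None, seq.id, frozenset(present)))
    return TGMappingSet(label, frozenset(entries))


def motifs_for_source_tgs(network: Iterable, motifs: Sequence) -> dict:
    """Map each source TG to the motif definitions of its regulating TF(s)."""
    by_tf = group_motifs(motifs)
    by_tg: dict = {}
    for link in network:
        by_tg.setdefault(link.tg_id, [])
        for motif in by_tf.get(link.tf_id, []):
            if motif not in by_tg[link.tg_id]:
                by_tg[link.tg_id].append(motif)
    return by_tg


def map_tg_bl_bs(
    tgbl: TGMappingSet,
    target_seqs: Sequence,
    tf_motifs_by_source_tg: Mapping,
    strands: str = "both",
) -> TGMappingSet:
    """Refine TGbl by requiring a motif of the source TG's regulator(s).

    An entry survives iff its target sequence contains at least one motif of
    the TF(s) regulating that source TG in the source network.  Source TGs
    with no associated motifs are dropped with a warning — not every source
    gene carries a known motif of its regulator.
    """
    if tgbl.label != "TGbl":
        raise ValueError(f"expected a TGbl set, got {tgbl.label}")
    seq_by_id = {s.id: s for s in target_seqs}
    presence_cache: dict = {}
    entries = set()
    for source_id, target_id, _ in tgbl.entries:
        motifs = tf_motifs_by_source_tg.get(source_id)
        if not motifs:
            logger.warning(
                "source TG %s has no regulator motifs; dropped from TGblbs", source_id
            )
            continue
        seq = seq_by_id.get(target_id)
        if seq is None:
            logger.warning("target sequence %s not provided; entry dropped", target_id)
            continue
        key = (target_id, frozenset(m.motif_id for m in motifs))
        if key not in presence_cache:
            presence_cache[key] = frozenset(contains_any(seq, motifs, strands))
        present = presence_cache[key]
        if present:
            entries.add((source_id, target_id, present))
    return TGMappingSet("TGblbs", frozenset(entries))
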