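"""Combine mapped TFs and mapped TGs into predicted target-genome links.

For every signed source link TF -> TG the motifs of the TF that actually occur
in the source TG are collected; a target link is predicted for every mapped
TF counterpart and every candidate target gene that contains at least one of
those motifs.  The regulation sign is inherited from the source link.

Candidate target genes depend on the TG set kind: similarity-based sets
(TGbl/TGblbs) restrict candidates to targets mapped from *this* source TG;
motif-only sets (TGbs/TGpr/TGgalf) carry no source association, so every
entry is a candidate — which is exactly why those combinations explode in
link count and need expression-based confirmation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import NetworkLink, Sign, group_motifs
from .motif_scan import contains_any
from .tf_mapping import TFMappingSet
from .tg_mapping import MOTIF_ONLY_LABELS, TGMappingSet

__all__ = ["PredictedLink", "IntegrationResult", "motifs_in_source_tg", "integrate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedLink:
    """A mapped regulatory link in the target genome."""

    source_tf_id: str
    source_tg_id: str
    target_tf_id: str
    target_tg_id: str
    sign: Sign
    supporting_motif_ids: frozenset
    provenance: str  # e.g. "TFsf-TGblbs"

    def __post_init__(self) -> None:
        if not self.supporting_motif_ids:
            raise ValueError("a predicted link needs >= 1 supporting motif")

    @property
    def target_key(self) -> tuple:
        return (self.target_tf_id, self.target_tg_id, self.sign)


@dataclass
class IntegrationResult:
    """Predicted links plus bookkeeping on source links that could not map."""

    links: list
    provenance: str
    n_source_links: int = 0
    n_skipped_no_motif: int = 0
    n_skipped_missing_seq: int = 0

    def __iter__(self):
        return iter(self.links)

    def __len__(self) -> int:
        return len(self.links)


def motifs_in_source_tg(
    link: NetworkLink,
    motifs: Sequence,
    source_tg_seq,
    strands: str = "both",
) -> set:
    """Ids of the TF's motifs that occur in the source TG sequence."""
    own = [m for m in motifs if m.tf_id == link.tf_id]
    if not own:
        return set()
    return contains_any(source_tg_seq, own, strands)


def integrate(
    source_network: Iterable,
    tf_map: TFMappingSet,
    tg_map: TGMappingSet,
    motifs: Sequence,
    source_tg_seqs: Sequence,
    target_seqs: Sequence,
    strands: str = "both",
    provenance: str | None = None,
) -> IntegrationResult:
    """Predict target-genome links for every mappable source link.

    Duplicate predictions onto the same (target TF, target TG, sign) within
    one run are collapsed, with supporting motif sets unioned and the
    lexicographically smallest source pair retained.
    """
    label = f"{tf_map.label}-{tg_map.label}"
    if provenance is not None and provenance != label:
        raise ValueError(
            f"requested provenance {provenance!r} does not match mapping sets "
            f"({label})"
        )
    motif_only = tg_map.label in MOTIF_ONLY_LABELS
    by_tf = group_motifs(motifs)
    source_seq_by_id = {s.id: s for s in source_tg_seqs}
    target_seq_by_id = {s.id: s for s in target_seqs}
    motif_by_id = {m.motif_id: m for m in motifs}

    # presence of one motif on one target sequence, computed at most once
    presence_cache: dict = {}

    def target_has(target_id: str, motif_id: str) -> bool:
        key = (target_id, motif_id)
        if key not in presence_cache:
            seq = target_seq_by_id.get(target_id)
            presence_cache[key] = bool(
                seq is not None
                and contains_any(seq, [motif_by_id[motif_id]], strands)
            )
        return presence_cache[key]

    collapsed: dict = {}
    result = IntegrationResult(links=[], provenance=label)
    for link in source_network:
        result.n_source_links += 1
        tf_motifs = by_tf.get(link.tf_id, [])
        if not tf_motifs:
            result.n_skipped_no_motif += 1
            continue
        source_seq = source_seq_by_id.get(link.tg_id)
        if source_seq is None:
            logger.warning("source TG %s has no sequence; link skipped", link.tg_id)
            result.n_skipped_missing_seq += 1
            continue
        motifs_present = motifs_in_source_tg(link, tf_motifs, source_seq, strands)
        if not motifs_present:
            result.n_skipped_no_motif += 1
            continue
        target_tfs = sorted(tf_map.targets_of(link.tf_id))
        if not target_tfs:
            continue
        if motif_only:
            candidates = sorted(tg_map.distinct_targets)
        else:
            candidates = sorted(tg_map.targets_of(link.tg_id))
        for target_tg in candidates:
            supporting = frozenset(
                m for m in motifs_present if target_has(target_tg, m)
            )
            if not supporting:
                continue
            for target_tf in target_tfs:
                key = (target_tf, target_tg, link.sign)
                prev = collapsed.get(key)
                if prev is None:
                    collapsed[key] = (link.tf_id, link.tg_id, supporting)
                else:
                    src = min(prev[:2], (link.tf_id, link.tg_id))
                    collapsed[key] = (src[0], src[1], prev[2] | supporting)

    for (target_tf, target_tg, sign), (src_tf, src_tg, supporting) in sorted(
        collapsed.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].symbol)
    ):
        result.links.append(
            PredictedLink(
                source_tf_id=src_tf,
                source_tg_id=src_tg,
                target_tf_id=target_tf,
                target_tg_id=target_tg,
                sign=sign,
                supporting_motif_ids=supporting,
                provenance=label,
            )
        )
    return result
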