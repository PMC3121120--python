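"""Locate IUPAC consensus binding-site motifs on nucleotide sequences.

Matching semantics: a motif letter matches a sequence letter iff the base set
denoted by the sequence letter is a subset of the base set denoted by the
motif letter.  A degenerate base in the *sequence* (e.g. the N-runs of draft
genomes) therefore only matches a motif position that is at least as
permissive, which prevents spurious matches through ambiguity runs.

Coordinates are 0-based half-open on the forward strand; minus-strand
occurrences are found by scanning the reverse complement of the motif and are
reported in forward-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import Alphabet, MotifDefinition, SequenceRecord

__all__ = [
    "MotifOccurrence",
    "iupac_match",
    "reverse_complement",
    "scan_sequence",
    "contains_any",
    "IUPAC_BITS",
]

# Each IUPAC letter as a 4-bit base set (A=1, C=2, G=4, T=8).
IUPAC_BITS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111,
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_BITS_LUT = np.zeros(128, dtype=np.uint8)
for _letter, _bits in IUPAC_BITS.items():
    _BITS_LUT[ord(_letter)] = _bits


@dataclass(frozen=True)
class MotifOccurrence:
    """One match of a motif on a sequence (forward-strand coordinates)."""

    motif_id: str
    seq_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    matched_text: str


def iupac_match(code: str, base: str) -> bool:
    """True iff the base set of ``base`` is contained in that of ``code``."""
    try:
        code_bits = IUPAC_BITS[code]
        base_bits = IUPAC_BITS[base]
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC letter {exc.args[0]!r}") from exc
    return base_bits & ~code_bits == 0


def reverse_complement(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (or plain DNA) string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(consensus))
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC letter {exc.args[0]!r}") from exc


def _encode(text: str) -> np.ndarray:
    arr = _BITS_LUT[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = text[int(np.argmax(arr == 0))]
        raise ValueError(f"illegal IUPAC letter {bad!r}")
    return arr


def _match_starts(seq_bits: np.ndarray, motif_bits: np.ndarray) -> np.ndarray:
    """Start indices where every window position passes the subset test."""
    k = len(motif_bits)
    if k > len(seq_bits):
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, k)
    ok = ((windows & ~motif_bits) == 0).all(axis=1)
    return np.flatnonzero(ok)


def scan_sequence(
    motif: MotifDefinition,
    seq: SequenceRecord,
    strands: str = "both",
) -> list:
    """All occurrences of ``motif`` on ``seq``, sorted by (start, strand).

    ``strands`` is ``"forward"`` or ``"both"``; with ``"both"`` the reverse
    complement of the consensus is also scanned on the forward sequence and
    matches are reported with strand ``'-'``.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    if seq.alphabet is not Alphabet.NUCLEOTIDE:
        raise ValueError(f"cannot scan {seq.alphabet.value} sequence {seq.id!r}")
    k = len(motif.consensus)
    if k > len(seq.residues) or k == 0:
        return []
    seq_bits = _encode(seq.residues)
    occurrences = []
    for strand, consensus in (
        ("+", motif.consensus),
        ("-", reverse_complement(motif.consensus)),
    ):
        if strand == "-" and strands != "both":
            continue
        for start in _match_starts(seq_bits, _encode(consensus)):
            start = int(start)
            occurrences.append(
                MotifOccurrence(
                    motif_id=motif.motif_id,
                    seq_id=seq.id,
                    start=start,
                    end=start + k,
                    strand=strand,
                    matched_text=seq.residues[start:start + k],
                )
            )
    occurrences.sort(key=lambda o: (o.start, o.strand))
    return occurrences


def contains_any(seq: SequenceRecord, motifs: Iterable, strands: str = "both") -> set:
    """Ids of the motifs with at least one occurrence on ``seq``.

    Downstream mapping uses presence/absence only, never occurrence counts.
    """
    present: set = set()
    for motif in motifs:
        if motif.motif_id in present:
            continue
        if scan_sequence(motif, seq, strands):
            present.add(motif.motif_id)
    return present
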