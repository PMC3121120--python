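"""Readers and writers for every external file the pipeline touches.

All tabular formats are plain TSV with a ``#``-prefixed header line; sequence
data is plain FASTA.  Readers are strict (malformed input is a hard error with
enough context to locate it) and order-preserving; writers sort by primary id
so that identical in-memory objects always produce byte-identical files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "SimilarityHit",
    "MotifDefinition",
    "Sign",
    "NetworkLink",
    "AnnotationRecord",
    "ExpressionCall",
    "ExpressionMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_similarity_table",
    "write_similarity_table",
    "read_motif_table",
    "write_motif_table",
    "group_motifs",
    "read_network",
    "write_network",
    "read_annotations",
    "write_annotations",
    "read_expression_matrix",
    "write_expression_matrix",
    "IUPAC_NUCLEOTIDES",
]

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
# 20 standard amino acids plus the common ambiguity/rare codes.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class Alphabet(str, enum.Enum):
    NUCLEOTIDE = "nucleotide"
    PROTEIN = "protein"

    @property
    def residues(self) -> frozenset:
        return IUPAC_NUCLEOTIDES if self is Alphabet.NUCLEOTIDE else PROTEIN_ALPHABET


@dataclass(frozen=True)
class SequenceRecord:
    """One identified sequence from a FASTA source, residues upper-cased."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.NUCLEOTIDE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        bad = set(self.residues) - self.alphabet.residues
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: illegal {self.alphabet.value} residue(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SimilarityHit:
    """One line of a 12-column BLAST-tabular (outfmt 6) style hit table.

    Coordinates are 1-based inclusive, following the tabular dialect.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise FormatError(f"hit {self.query_id}/{self.subject_id}: q_start > q_end")
        if self.alignment_length < 1:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: alignment_length < 1"
            )
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}/{self.subject_id}: negative evalue")


@dataclass(frozen=True)
class MotifDefinition:
    """A TF's binding-site motif written as an IUPAC consensus string."""

    tf_id: str
    motif_id: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise FormatError(f"motif {self.motif_id!r}: empty consensus")
        bad = set(self.consensus) - IUPAC_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"motif {self.motif_id!r}: illegal IUPAC character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


class Sign(str, enum.Enum):
    """Type of a regulatory relationship: activation (+) or repression (-)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @property
    def symbol(self) -> str:
        return "+" if self is Sign.POSITIVE else "-"

    @classmethod
    def from_symbol(cls, token: str) -> "Sign":
        if token == "+":
            return cls.POSITIVE
        if token == "-":
            return cls.NEGATIVE
        raise FormatError(f"unknown regulation sign {token!r} (expected '+' or '-')")


@dataclass(frozen=True)
class NetworkLink:
    """A signed TF -> TG edge of the source regulatory network."""

    tf_id: str
    tg_id: str
    sign: Sign


@dataclass(frozen=True)
class AnnotationRecord:
    """Protein family/subfamily labels for one sequence (subfamilies nest)."""

    seq_id: str
    family_id: str | None = None
    subfamily_id: str | None = None

    def __post_init__(self) -> None:
        if self.subfamily_id is not None and self.family_id is None:
            raise FormatError(
                f"annotation {self.seq_id!r}: subfamily without family "
                "(subfamilies are nested within families)"
            )


class ExpressionCall(str, enum.Enum):
    """Ternary expression call of one gene in one experiment."""

    EXPRESSED = "Y"
    NOT_EXPRESSED = "N"
    ABSENT = "ab"


_CALL_TOKENS = {c.value: c for c in ExpressionCall}


@dataclass
class ExpressionMatrix:
    """Gene x experiment grid of ternary expression calls.

    Genes that the matrix does not know about behave as absent in every
    experiment, so links whose endpoints lack expression data are simply
    ignored downstream rather than erroring.
    """

    calls: pd.DataFrame  # index: gene ids, columns: experiment ids, values: ExpressionCall

    def __post_init__(self) -> None:
        bad = set(self.calls.values.ravel()) - set(ExpressionCall)
        if bad:
            raise FormatError(f"expression matrix holds non-call values: {bad}")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise FormatError("expression matrix has duplicate gene or experiment ids")

    @property
    def gene_ids(self) -> list:
        return list(self.calls.index)

    @property
    def experiment_ids(self) -> list:
        return list(self.calls.columns)

    @property
    def n_experiments(self) -> int:
        return self.calls.shape[1]

    def call(self, gene_id: str, experiment_id: str) -> ExpressionCall:
        if gene_id not in self.calls.index:
            return ExpressionCall.ABSENT
        return self.calls.at[gene_id, experiment_id]

    def calls_for(self, gene_id: str) -> list:
        """All calls for one gene in experiment order (absent if unknown)."""
        if gene_id not in self.calls.index:
            return [ExpressionCall.ABSENT] * self.n_experiments
        return list(self.calls.loc[gene_id])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: Alphabet | str) -> list:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Ids are the first whitespace-delimited token of each header; residues are
    upper-cased and validated against the declared alphabet.  Duplicate ids
    and illegal residues are hard errors.
    """
    alphabet = Alphabet(alphabet)
    path = Path(path)
    records: list = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - alphabet.residues
        if bad:
            raise FormatError(
                f"{path}: sequence {rec.id!r} near line "
                f"{_find_line(path, sorted(bad)[0], rec.id)}: illegal "
                f"{alphabet.value} residue(s) {sorted(bad)}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, alphabet, desc))
    return records


def _find_line(path: Path, char: str, seq_id: str) -> int:
    """Best-effort line number of an offending residue, for error messages."""
    in_target = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_target = line[1:].split()[0] == seq_id if line[1:].split() else False
        elif in_target and char in line.upper():
            return lineno
    return 0


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records sorted by id, wrapping residues at ``width`` columns."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in sorted(records, key=lambda r: r.id):
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV helpers

_TSV_ENCODING = dict(encoding="utf-8", newline="\n")


def _data_lines(path: Path):
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        yield lineno, raw


# ---------------------------------------------------------------------------
# Similarity hit tables (BLAST outfmt 6 dialect)

_HIT_HEADER = ("#query_id\tsubject_id\tpercent_identity\talignment_length\t"
               "mismatches\tgap_opens\tq_start\tq_end\ts_start\ts_end\tevalue\tscore")


def read_similarity_table(path) -> list:
    """Parse a 12-column tab-delimited hit table, preserving line order."""
    path = Path(path)
    hits: list = []
    for lineno, raw in _data_lines(path):
        cols = raw.split("\t")
        if len(cols) != 12:
            raise FormatError(
                f"{path}:{lineno}: expected 12 tab-delimited columns, got {len(cols)}"
            )
        try:
            hits.append(
                SimilarityHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    score=float(cols[11]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _fmt_float(x: float) -> str:
    return format(x, ".6g")


def write_similarity_table(hits: Iterable, path) -> None:
    path = Path(path)
    with path.open("w", **_TSV_ENCODING) as fh:
        fh.write(_HIT_HEADER + "\n")
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id, h.s_start)):
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _fmt_float(h.percent_identity),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt_float(h.evalue),
                        _fmt_float(h.score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Motif tables


def read_motif_table(path) -> list:
    """Read (tf_id, motif_id, consensus) rows into MotifDefinition objects."""
    path = Path(path)
    motifs: list = []
    for lineno, raw in _data_lines(path):
        cols = raw.split("\t")
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        try:
            motifs.append(MotifDefinition(*cols))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return motifs


def write_motif_table(motifs: Iterable, path) -> None:
    path = Path(path)
    with path.open("w", **_TSV_ENCODING) as fh:
        fh.write("#tf_id\tmotif_id\tconsensus\n")
        for m in sorted(motifs, key=lambda m: (m.tf_id, m.motif_id)):
            fh.write(f"{m.tf_id}\t{m.motif_id}\t{m.consensus}\n")


def group_motifs(motifs: Iterable) -> dict:
    """Group motif definitions by owning TF id (insertion order preserved)."""
    by_tf: dict = {}
    for m in motifs:
        by_tf.setdefault(m.tf_id, []).append(m)
    return by_tf


# ---------------------------------------------------------------------------
# Networks


def read_network(path) -> list:
    """Read the signed source-network edge list (tf_id, tg_id, +/-)."""
    path = Path(path)
    links: list = []
    seen: set = set()
    for lineno, raw in _data_lines(path):
        cols = raw.split("\t")
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        try:
            link = NetworkLink(cols[0], cols[1], Sign.from_symbol(cols[2]))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        key = (link.tf_id, link.tg_id, link.sign)
        if key in seen:
            raise FormatError(
                f"{path}:{lineno}: duplicate link {link.tf_id}->{link.tg_id} "
                f"({link.sign.symbol})"
            )
        seen.add(key)
        links.append(link)
    return links


def write_network(links: Iterable, path) -> None:
    path = Path(path)
    with path.open("w", **_TSV_ENCODING) as fh:
        fh.write("#tf_id\ttg_id\tsign\n")
        for l in sorted(links, key=lambda l: (l.tf_id, l.tg_id, l.sign.symbol)):
            fh.write(f"{l.tf_id}\t{l.tg_id}\t{l.sign.symbol}\n")


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path) -> dict:
    """Read (seq_id, family, subfamily) rows; '-' marks a missing label."""
    path = Path(path)
    annots: dict = {}
    for lineno, raw in _data_lines(path):
        cols = raw.split("\t")
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        seq_id, family, subfamily = cols
        if seq_id in annots:
            raise FormatError(f"{path}:{lineno}: duplicate annotation for {seq_id!r}")
        try:
            annots[seq_id] = AnnotationRecord(
                seq_id,
                None if family == "-" else family,
                None if subfamily == "-" else subfamily,
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return annots


def write_annotations(annots, path) -> None:
    records = annots.values() if isinstance(annots, Mapping) else annots
    path = Path(path)
    with path.open("w", **_TSV_ENCODING) as fh:
        fh.write("#seq_id\tfamily_id\tsubfamily_id\n")
        for a in sorted(records, key=lambda a: a.seq_id):
            fh.write(
                f"{a.seq_id}\t{a.family_id or '-'}\t{a.subfamily_id or '-'}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_matrix(path, numeric_threshold: float | None = None) -> ExpressionMatrix:
    """Read a gene x experiment TSV of expression calls.

    In ternary mode (default) cells must be one of ``Y``/``N``/``ab``.  When
    ``numeric_threshold`` is given, numeric cells map to expressed when the
    value is >= the threshold (inclusive boundary), not-expressed below it,
    and an empty cell means absent.
    """
    path = Path(path)
    raw_lines = [
        (lineno, raw)
        for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1)
        if raw.strip()
    ]
    if not raw_lines:
        raise FormatError(f"{path}: empty expression matrix")
    header = raw_lines[0][1].lstrip("#").split("\t")
    lines = [(n, r) for n, r in raw_lines[1:] if not r.startswith("#")]
    lines.insert(0, raw_lines[0])  # keep indexing below uniform
    experiments = header[1:]
    genes: list = []
    rows: list = []
    for lineno, raw in lines[1:]:
        cols = raw.split("\t")
        if len(cols) != len(header):
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cols)} columns, "
                f"header has {len(header)})"
            )
        genes.append(cols[0])
        row = []
        for cell in cols[1:]:
            if numeric_threshold is None:
                if cell not in _CALL_TOKENS:
                    raise FormatError(
                        f"{path}:{lineno}: unknown expression token {cell!r} "
                        "(expected Y, N or ab)"
                    )
                row.append(_CALL_TOKENS[cell])
            else:
                if cell == "":
                    row.append(ExpressionCall.ABSENT)
                else:
                    try:
                        value = float(cell)
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: {exc}") from exc
                    row.append(
                        ExpressionCall.EXPRESSED
                        if value >= numeric_threshold
                        else ExpressionCall.NOT_EXPRESSED
                    )
        rows.append(row)
    frame = pd.DataFrame(rows, index=genes, columns=experiments, dtype=object)
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    frame = matrix.calls.sort_index()
    with path.open("w", **_TSV_ENCODING) as fh:
        fh.write("#gene_id\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for gene, row in frame.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(c.value for c in row) + "\n")
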