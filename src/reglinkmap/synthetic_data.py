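"""Generate paired source/target scenarios with a known truth table.

A scenario emulates the data regime the pipeline was designed for: a source
genome with a signed TF -> TG regulatory network and per-TF binding-site
motifs, a target genome containing mutated homologs of some source genes plus
unrelated decoy sequences, nested family/subfamily annotations, promoter
sequences, and a ternary expression matrix whose per-experiment patterns
confirm or contradict the conserved links at configured rates.

Construction guarantees (what makes the truth table exact):

* every source TG carries one planted motif instance of each regulating TF;
* a conserved link's motif instance is re-planted intact in the target
  homolog (and its promoter), so a noiseless scenario is recovered with
  recall 1;
* every *other* motif occurrence — chance matches in background sequence and
  motif instances surviving mutation in non-conserved targets — is knocked
  out by point mutations, so predicted links beyond the planted truth cannot
  arise from the generator itself.

Motif consensus strings are concrete (ambiguity-free) and pairwise distinct
including reverse complements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    Alphabet,
    AnnotationRecord,
    ExpressionCall,
    ExpressionMatrix,
    MotifDefinition,
    NetworkLink,
    SequenceRecord,
    Sign,
    write_annotations,
    write_expression_matrix,
    write_fasta,
    write_motif_table,
    write_network,
)
from .motif_scan import reverse_complement, scan_sequence

__all__ = [
    "ScenarioParams",
    "ScenarioTruth",
    "Scenario",
    "generate_scenario",
    "mutate_sequence",
    "plant_motif",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of the scenario generator; defaults are the study conditions.

    The expression block mirrors a small-compendium regime (43 experiments,
    as for a plant target genome); conservation fractions and the 5% per-base
    substitution rate describe moderately diverged homolog pairs.
    """

    n_tf: int = 10
    n_tg: int = 50
    seq_len_tf: int = 300
    seq_len_tg: int = 400
    promoter_len: int = 200
    motifs_per_tf: int = 2
    motif_len: int = 8
    links_per_tf: int = 5
    frac_positive: float = 0.7
    frac_tf_conserved: float = 0.8
    frac_tg_conserved: float = 0.8
    frac_link_conserved: float = 0.6
    substitution_rate: float = 0.05
    n_decoy_seqs: int = 20
    decoy_family_rate: float = 0.2
    n_experiments: int = 43
    p_confirm_true: float = 0.8
    p_contradict_true: float = 0.1
    p_absent: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_positive", "frac_tf_conserved", "frac_tg_conserved",
            "frac_link_conserved", "substitution_rate", "decoy_family_rate",
            "p_confirm_true", "p_contradict_true", "p_absent",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.p_confirm_true + self.p_contradict_true > 1.0:
            raise ValueError("p_confirm_true + p_contradict_true must be <= 1")
        for name in ("n_tf", "n_tg", "motifs_per_tf", "motif_len",
                     "links_per_tf", "n_decoy_seqs", "n_experiments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motif_len > min(self.seq_len_tg, self.promoter_len):
            raise ValueError("motif_len exceeds the shortest plantable sequence")
        if self.links_per_tf > self.n_tg:
            raise ValueError("links_per_tf cannot exceed n_tg")


@dataclass(frozen=True)
class ScenarioTruth:
    """What was planted: homolog pairs, conserved links, motif placements."""

    tf_homolog_pairs: frozenset  # (source_tf_id, target_seq_id)
    tg_homolog_pairs: frozenset  # (source_tg_id, target_seq_id)
    conserved_links: frozenset   # (target_tf_id, target_tg_id, Sign)
    planted_occurrences: tuple   # (kind, seq_id, motif_id, start)


@dataclass
class Scenario:
    """A complete in-memory fixture bundle."""

    params: ScenarioParams
    source_tfs: list
    source_tgs: list
    target_seqs: list
    promoters: list
    motifs: list
    network: list
    source_annotations: dict
    target_annotations: dict
    expression: ExpressionMatrix
    truth: ScenarioTruth

    def write(self, out_dir) -> None:
        """Write the bundle as plain-text files plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.source_tfs, out / "source_tf.fa")
        write_fasta(self.source_tgs, out / "source_tg.fa")
        write_fasta(self.target_seqs, out / "target.fa")
        write_fasta(self.promoters, out / "promoters.fa")
        write_motif_table(self.motifs, out / "motifs.tsv")
        write_network(self.network, out / "network.tsv")
        write_annotations(self.source_annotations, out / "annotations_source.tsv")
        write_annotations(self.target_annotations, out / "annotations_target.tsv")
        write_expression_matrix(self.expression, out / "expression.tsv")
        with (out / "truth.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("#kind\ta\tb\tc\n")
            for s, t in sorted(self.truth.tf_homolog_pairs):
                fh.write(f"tf_homolog\t{s}\t{t}\t-\n")
            for s, t in sorted(self.truth.tg_homolog_pairs):
                fh.write(f"tg_homolog\t{s}\t{t}\t-\n")
            for tf, tg, sign in sorted(
                self.truth.conserved_links, key=lambda x: (x[0], x[1], x[2].symbol)
            ):
                fh.write(f"conserved_link\t{tf}\t{tg}\t{sign.symbol}\n")
        manifest = {"params": asdict(self.params),
                    "counts": {
                        "source_tfs": len(self.source_tfs),
                        "source_tgs": len(self.source_tgs),
                        "target_seqs": len(self.target_seqs),
                        "network_links": len(self.network),
                        "conserved_links": len(self.truth.conserved_links),
                    },
                    "rng": "numpy PCG64 (default_rng), integer seed"}
        (out / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# sequence-level primitives


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with a uniformly chosen *different* base
    with probability ``rate`` (no indels)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        current = chars[i]
        options = [b for b in _BASES if b != current]
        chars[i] = options[rng.integers(len(options))]
    return "".join(chars)


def plant_motif(seq: str, motif: str, position: int, rng: np.random.Generator) -> str:
    """Overwrite a window with a concrete instantiation of an IUPAC motif.

    Each degenerate letter is realized uniformly from its base set, so the
    scanner is guaranteed to find the motif at ``position``.
    """
    if position < 0 or position + len(motif) > len(seq):
        raise ValueError(
            f"cannot plant length-{len(motif)} motif at {position} "
            f"in length-{len(seq)} sequence"
        )
    from .motif_scan import IUPAC_BITS

    instance = []
    for letter in motif:
        try:
            bits = IUPAC_BITS[letter]
        except KeyError as exc:
            raise ValueError(f"illegal IUPAC letter {exc.args[0]!r}") from exc
        choices = [b for i, b in enumerate(_BASES) if bits >> i & 1]
        instance.append(choices[rng.integers(len(choices))])
    return seq[:position] + "".join(instance) + seq[position + len(motif):]


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=length))


def _scrub(
    seq: str,
    motifs: Iterable,
    protected: dict,
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> str:
    """Destroy every motif occurrence except the protected planted ones.

    ``protected`` maps motif_id -> set of allowed forward-strand starts.
    One base inside each offending window (outside protected intervals) is
    mutated; rescanning repeats until clean because a fix can itself create
    a new match.
    """
    intervals = sorted(
        (start, start + len(m.consensus))
        for m in motifs
        for start in protected.get(m.motif_id, ())
    )

    def is_protected(pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in intervals)

    current = seq
    for _ in range(max_rounds):
        dirty = False
        record = SequenceRecord("_scrub", current)
        for motif in motifs:
            for occ in scan_sequence(motif, record, "both"):
                if occ.strand == "+" and occ.start in protected.get(occ.motif_id, ()):
                    continue
                positions = [p for p in range(occ.start, occ.end) if not is_protected(p)]
                if not positions:
                    raise RuntimeError(
                        f"cannot scrub occurrence of {occ.motif_id} at {occ.start}: "
                        "window fully protected"
                    )
                p = positions[rng.integers(len(positions))]
                base = current[p]
                options = [b for b in _BASES if b != base]
                current = current[:p] + options[rng.integers(3)] + current[p + 1:]
                dirty = True
        if not dirty:
            return current
    raise RuntimeError("scrubbing did not converge")


# ---------------------------------------------------------------------------
# generator


def _make_motifs(params: ScenarioParams, rng: np.random.Generator) -> list:
    """Distinct concrete motifs, no two equal or reverse-complementary."""
    used: set = set()
    motifs = []
    for i in range(params.n_tf):
        tf_id = f"STF{i:03d}"
        for j in range(params.motifs_per_tf):
            for _ in range(1000):
                consensus = _random_seq(params.motif_len, rng)
                rc = reverse_complement(consensus)
                if consensus != rc and consensus not in used and rc not in used:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a fresh motif")
            used.add(consensus)
            used.add(rc)
            motifs.append(MotifDefinition(tf_id, f"{tf_id}_m{j}", consensus))
    return motifs


def _wire_network(params: ScenarioParams, rng: np.random.Generator) -> list:
    """Sample links; TGs are partitioned across TFs whenever possible so
    each TG has a single regulator (keeps expression calibration exact)."""
    tg_ids = [f"STG{i:03d}" for i in range(params.n_tg)]
    links = []
    if params.n_tf * params.links_per_tf <= params.n_tg:
        order = list(rng.permutation(params.n_tg))
        for i in range(params.n_tf):
            chunk = order[i * params.links_per_tf:(i + 1) * params.links_per_tf]
            for j in chunk:
                sign = Sign.POSITIVE if rng.random() < params.frac_positive else Sign.NEGATIVE
                links.append(NetworkLink(f"STF{i:03d}", tg_ids[j], sign))
    else:
        for i in range(params.n_tf):
            chosen = rng.choice(params.n_tg, size=params.links_per_tf, replace=False)
            for j in sorted(int(x) for x in chosen):
                sign = Sign.POSITIVE if rng.random() < params.frac_positive else Sign.NEGATIVE
                links.append(NetworkLink(f"STF{i:03d}", tg_ids[j], sign))
    links.sort(key=lambda l: (l.tf_id, l.tg_id))
    return links


def _free_position(occupied: list, seq_len: int, k: int, rng: np.random.Generator) -> int:
    for _ in range(200):
        pos = int(rng.integers(0, seq_len - k + 1))
        if all(pos + k <= lo or pos >= hi for lo, hi in occupied):
            occupied.append((pos, pos + k))
            return pos
    raise RuntimeError("could not find a free motif slot; sequence too crowded")


def generate_scenario(params: ScenarioParams = ScenarioParams()) -> Scenario:
    """Build a complete scenario; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    motifs = _make_motifs(params, rng)
    motifs_by_tf: dict = {}
    for m in motifs:
        motifs_by_tf.setdefault(m.tf_id, []).append(m)
    network = _wire_network(params, rng)

    tf_ids = [f"STF{i:03d}" for i in range(params.n_tf)]
    tg_ids = [f"STG{i:03d}" for i in range(params.n_tg)]

    # --- source sequences -------------------------------------------------
    planted: list = []  # (kind, seq_id, motif_id, start)
    source_tf_seqs = {}
    for tf_id in tf_ids:
        raw = _random_seq(params.seq_len_tf, rng)
        source_tf_seqs[tf_id] = _scrub(raw, motifs, {}, rng)

    links_by_tg: dict = {}
    for link in network:
        links_by_tg.setdefault(link.tg_id, []).append(link)

    source_tg_seqs = {}
    source_plant: dict = {}  # tg_id -> {link(tf,tg) -> (motif, pos)}
    for tg_id in tg_ids:
        raw = _random_seq(params.seq_len_tg, rng)
        occupied: list = []
        plants: dict = {}
        protected: dict = {}
        for link in links_by_tg.get(tg_id, []):
            own = motifs_by_tf[link.tf_id]
            motif = own[rng.integers(len(own))]
            pos = _free_position(occupied, params.seq_len_tg, len(motif), rng)
            raw = plant_motif(raw, motif.consensus, pos, rng)
            plants[(link.tf_id, link.tg_id)] = (motif, pos)
            protected.setdefault(motif.motif_id, set()).add(pos)
            planted.append(("source", tg_id, motif.motif_id, pos))
        source_tg_seqs[tg_id] = _scrub(raw, motifs, protected, rng)
        source_plant[tg_id] = plants

    # --- conservation choices --------------------------------------------
    n_tf_cons = int(round(params.frac_tf_conserved * params.n_tf))
    n_tg_cons = int(round(params.frac_tg_conserved * params.n_tg))
    conserved_tfs = sorted(
        tf_ids[i] for i in rng.choice(params.n_tf, size=n_tf_cons, replace=False)
    )
    conserved_tgs = sorted(
        tg_ids[i] for i in rng.choice(params.n_tg, size=n_tg_cons, replace=False)
    )
    conserved_links = []
    for link in network:
        if link.tf_id in conserved_tfs and link.tg_id in conserved_tgs:
            if rng.random() < params.frac_link_conserved:
                conserved_links.append(link)

    homolog = lambda source_id: f"T{source_id}"

    # --- target sequences -------------------------------------------------
    target_seqs = []
    for tf_id in conserved_tfs:
        mutated = mutate_sequence(source_tf_seqs[tf_id], params.substitution_rate, rng)
        target_seqs.append(SequenceRecord(homolog(tf_id), _scrub(mutated, motifs, {}, rng)))

    cons_links_by_tg: dict = {}
    for link in conserved_links:
        cons_links_by_tg.setdefault(link.tg_id, []).append(link)

    promoters = []
    for tg_id in conserved_tgs:
        mutated = mutate_sequence(source_tg_seqs[tg_id], params.substitution_rate, rng)
        protected: dict = {}
        for link in cons_links_by_tg.get(tg_id, []):
            motif, pos = source_plant[tg_id][(link.tf_id, link.tg_id)]
            mutated = plant_motif(mutated, motif.consensus, pos, rng)
            protected.setdefault(motif.motif_id, set()).add(pos)
            planted.append(("target", homolog(tg_id), motif.motif_id, pos))
        target_seqs.append(
            SequenceRecord(homolog(tg_id), _scrub(mutated, motifs, protected, rng))
        )
        # promoter of the homolog, motif planted for conserved links only
        prom = _random_seq(params.promoter_len, rng)
        occupied = []
        prom_protected: dict = {}
        for link in cons_links_by_tg.get(tg_id, []):
            motif, _ = source_plant[tg_id][(link.tf_id, link.tg_id)]
            pos = _free_position(occupied, params.promoter_len, len(motif), rng)
            prom = plant_motif(prom, motif.consensus, pos, rng)
            prom_protected.setdefault(motif.motif_id, set()).add(pos)
            planted.append(("promoter", homolog(tg_id), motif.motif_id, pos))
        promoters.append(SequenceRecord(homolog(tg_id), _scrub(prom, motifs, prom_protected, rng)))

    for i in range(params.n_decoy_seqs):
        decoy_id = f"DEC{i:03d}"
        target_seqs.append(
            SequenceRecord(decoy_id, _scrub(_random_seq(params.seq_len_tg, rng), motifs, {}, rng))
        )
        promoters.append(
            SequenceRecord(decoy_id, _scrub(_random_seq(params.promoter_len, rng), motifs, {}, rng))
        )

    # --- annotations ------------------------------------------------------
    source_annotations = {
        tf_id: AnnotationRecord(tf_id, f"FAM{i:03d}", f"SUB{i:03d}")
        for i, tf_id in enumerate(tf_ids)
    }
    target_annotations = {}
    for tf_id in conserved_tfs:
        src = source_annotations[tf_id]
        target_annotations[homolog(tf_id)] = AnnotationRecord(
            homolog(tf_id), src.family_id, src.subfamily_id
        )
    for i in range(params.n_decoy_seqs):
        if rng.random() < params.decoy_family_rate and tf_ids:
            family = source_annotations[tf_ids[int(rng.integers(params.n_tf))]].family_id
            decoy_id = f"DEC{i:03d}"
            target_annotations[decoy_id] = AnnotationRecord(
                decoy_id, family, f"DECSUB{i:03d}"
            )

    # --- expression -------------------------------------------------------
    expression = _make_expression(
        params, rng,
        gene_ids=sorted(r.id for r in target_seqs),
        conserved_links=conserved_links,
        homolog=homolog,
    )

    truth = ScenarioTruth(
        tf_homolog_pairs=frozenset((tf, homolog(tf)) for tf in conserved_tfs),
        tg_homolog_pairs=frozenset((tg, homolog(tg)) for tg in conserved_tgs),
        conserved_links=frozenset(
            (homolog(l.tf_id), homolog(l.tg_id), l.sign) for l in conserved_links
        ),
        planted_occurrences=tuple(planted),
    )
    return Scenario(
        params=params,
        source_tfs=[SequenceRecord(i, source_tf_seqs[i]) for i in tf_ids],
        source_tgs=[SequenceRecord(i, source_tg_seqs[i]) for i in tg_ids],
        target_seqs=target_seqs,
        promoters=promoters,
        motifs=motifs,
        network=network,
        source_annotations=source_annotations,
        target_annotations=target_annotations,
        expression=expression,
        truth=truth,
    )


def _make_expression(params, rng, gene_ids, conserved_links, homolog) -> ExpressionMatrix:
    """Expression calls realizing per-link outcome rates for conserved links.

    A per-experiment latent call is drawn for each regulating TF with
    P(expressed) = p_confirm + p_contradict; given the TF call, each of its
    (single-regulator) TGs is set so that an activation link is Confirming
    with probability exactly p_confirm and Contradictory with p_contradict.
    Repression links have no Neutral cell in the rule table, so their
    informative mass is split Confirming:Contradictory in proportion
    p_confirm:p_contradict.  All other genes are expressed independently with
    probability one half; every gene is absent with probability p_absent.
    """
    p_c, p_x = params.p_confirm_true, params.p_contradict_true
    p_inf = p_c + p_x
    confirm_given_inf = p_c / p_inf if p_inf > 0 else 0.0

    experiments = [f"E{j:03d}" for j in range(params.n_experiments)]
    frame = pd.DataFrame(
        ExpressionCall.NOT_EXPRESSED, index=gene_ids, columns=experiments, dtype=object
    )
    link_tfs = sorted({homolog(l.tf_id) for l in conserved_links})
    ordered_links = sorted(conserved_links, key=lambda l: (l.tf_id, l.tg_id))
    driven = {homolog(l.tg_id) for l in conserved_links} | set(link_tfs)

    Y, N, AB = (ExpressionCall.EXPRESSED, ExpressionCall.NOT_EXPRESSED,
                ExpressionCall.ABSENT)
    for exp in experiments:
        tf_call = {tf: (Y if rng.random() < p_inf else N) for tf in link_tfs}
        assigned: set = set(link_tfs)
        for tf, call in tf_call.items():
            frame.at[tf, exp] = call
        for link in ordered_links:
            tg = homolog(link.tg_id)
            if tg in assigned:
                continue  # first regulator wins when a TG has several
            assigned.add(tg)
            t = tf_call[homolog(link.tf_id)]
            if link.sign is Sign.POSITIVE:
                if t is Y:
                    call = Y if rng.random() < confirm_given_inf else N
                else:
                    call = Y if rng.random() < 0.5 else N  # Neutral vs ignored
            else:
                confirm = rng.random() < confirm_given_inf
                call = (N if t is Y else Y) if confirm else (Y if t is Y else N)
            frame.at[tg, exp] = call
        for gene in gene_ids:
            if gene not in assigned and gene not in driven:
                frame.at[gene, exp] = Y if rng.random() < 0.5 else N
        for gene in gene_ids:
            if rng.random() < params.p_absent:
                frame.at[gene, exp] = AB
    return ExpressionMatrix(frame)
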