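"""End-to-end orchestration: map TFs and TGs, integrate, confirm, evaluate.

Two entry points: :func:`run_scenario` executes the whole pipeline on an
in-memory :class:`~reglinkmap.synthetic_data.Scenario` (used by tests and the
acceptance script), and :func:`run_pipeline` does the same from files on disk
for the command line, writing every stage artifact plus a run manifest.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .expression_confirmation import ConfirmationReport, TierConfig, confirm_links
from .io_formats import (
    read_annotations,
    read_expression_matrix,
    read_fasta,
    read_motif_table,
    read_network,
    write_similarity_table,
)
from .link_integration import IntegrationResult, integrate
from .similarity import DEFAULT_MAX_EVALUE, ScoringScheme, find_similar
from .tf_mapping import map_tf_bl, map_tf_family, map_tf_subfamily
from .tg_mapping import (
    map_tg_bl,
    map_tg_bl_bs,
    map_tg_motif,
    motifs_for_source_tgs,
)

__all__ = ["PipelineConfig", "PipelineRun", "run_scenario", "run_pipeline",
           "score_against_truth", "default_min_score"]

TF_MODES = {"bl": "TFbl", "f": "TFf", "sf": "TFsf"}
TG_MODES = {"bl": "TGbl", "bs": "TGbs", "blbs": "TGblbs", "pr": "TGpr", "galf": "TGgalf"}


def default_min_score(queries) -> float:
    """Half the median query length — far above the background local-alignment
    score of unrelated sequences, far below the score of a moderately
    diverged homolog under the default +1/-1/-2 scoring."""
    return 0.5 * statistics.median(len(q) for q in queries)


@dataclass
class PipelineRun:
    """Artifacts and stage counts of one pipeline execution."""

    tf_map: object
    tg_map: object
    integration: IntegrationResult
    report: ConfirmationReport
    tf_hits: list = field(default_factory=list)
    tg_hits: list = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "version": __version__,
            "provenance": self.integration.provenance,
            "n_mapped_tf_pairs": len(self.tf_map),
            "n_mapped_tfs": len(self.tf_map.distinct_targets),
            "n_mapped_tg_entries": len(self.tg_map),
            "n_mapped_tgs": len(self.tg_map.distinct_targets),
            "n_source_links": self.integration.n_source_links,
            "n_source_links_without_motif": self.integration.n_skipped_no_motif,
            "n_links_mapped": len(self.integration),
            **self.report.summary(),
        }


def _select_tf_map(mode, source_tfs, hits, max_evalue, source_annot, target_annot):
    tfbl = map_tf_bl(source_tfs, hits, max_evalue)
    if mode == "bl":
        return tfbl
    tff = map_tf_family(tfbl, source_annot, target_annot)
    if mode == "f":
        return tff
    return map_tf_subfamily(tff, source_annot, target_annot)


def run_scenario(
    scenario,
    tf_mode: str = "sf",
    tg_mode: str = "blbs",
    min_score_tf: float | None = None,
    min_score_tg: float | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    strands: str = "both",
    scheme: ScoringScheme = ScoringScheme(),
    tier_config: TierConfig = TierConfig(),
    discovered_motifs=None,
) -> PipelineRun:
    """Run map-tf -> map-tg -> integrate -> confirm on a scenario bundle.

    ``discovered_motifs`` supplies the externally discovered motif set for
    ``tg_mode="galf"``; the scenario's own motifs are used when omitted.
    """
    if tf_mode not in TF_MODES:
        raise ValueError(f"tf_mode must be one of {sorted(TF_MODES)}")
    if tg_mode not in TG_MODES:
        raise ValueError(f"tg_mode must be one of {sorted(TG_MODES)}")
    if min_score_tf is None:
        min_score_tf = default_min_score(scenario.source_tfs)
    if min_score_tg is None:
        min_score_tg = default_min_score(scenario.source_tgs)

    tf_hits = find_similar(scenario.source_tfs, scenario.target_seqs, scheme, min_score_tf)
    tf_map = _select_tf_map(
        tf_mode, scenario.source_tfs, tf_hits, max_evalue,
        scenario.source_annotations, scenario.target_annotations,
    )

    tg_hits = []
    if tg_mode in ("bl", "blbs"):
        tg_hits = find_similar(
            scenario.source_tgs, scenario.target_seqs, scheme, min_score_tg
        )
        tgbl = map_tg_bl(scenario.source_tgs, tg_hits, max_evalue)
        if tg_mode == "bl":
            tg_map = tgbl
        else:
            tg_map = map_tg_bl_bs(
                tgbl,
                scenario.target_seqs,
                motifs_for_source_tgs(scenario.network, scenario.motifs),
                strands,
            )
    elif tg_mode == "bs":
        tg_map = map_tg_motif(scenario.target_seqs, scenario.motifs, strands, "TGbs")
    elif tg_mode == "pr":
        tg_map = map_tg_motif(scenario.promoters, scenario.motifs, strands, "TGpr")
    else:  # galf
        motif_set = discovered_motifs if discovered_motifs is not None else scenario.motifs
        tg_map = map_tg_motif(scenario.promoters, motif_set, strands, "TGgalf")

    scan_db = scenario.promoters if tg_mode in ("pr", "galf") else scenario.target_seqs
    integration = integrate(
        scenario.network, tf_map, tg_map, scenario.motifs,
        scenario.source_tgs, scan_db, strands,
    )
    report = confirm_links(integration.links, scenario.expression, tier_config)
    return PipelineRun(
        tf_map=tf_map, tg_map=tg_map, integration=integration,
        report=report, tf_hits=tf_hits, tg_hits=tg_hits,
    )


def score_against_truth(integration: IntegrationResult, truth) -> dict:
    """Recall and precision of predicted (TF, TG, sign) triples vs truth."""
    predicted = {link.target_key for link in integration.links}
    true = set(truth.conserved_links)
    tp = len(predicted & true)
    return {
        "recall": tp / len(true) if true else None,
        "precision": tp / len(predicted) if predicted else None,
        "n_predicted": len(predicted),
        "n_true": len(true),
    }


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see the ``run`` subcommand)."""

    source_tf_fasta: str
    source_tg_fasta: str
    target_fasta: str
    motif_table: str
    network_table: str
    out_dir: str
    promoter_fasta: str | None = None
    source_annotations: str | None = None
    target_annotations: str | None = None
    expression_table: str | None = None
    discovered_motif_table: str | None = None
    tf_mode: str = "sf"
    tg_mode: str = "blbs"
    min_score_tf: float | None = None
    min_score_tg: float | None = None
    max_evalue: float = DEFAULT_MAX_EVALUE
    strands: str = "both"
    contradictory_weight: int = 2
    neutral_weight: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


class _FileScenario:
    """Adapter giving file-loaded inputs the scenario attribute surface."""

    def __init__(self, config: PipelineConfig):
        self.source_tfs = read_fasta(config.source_tf_fasta, "nucleotide")
        self.source_tgs = read_fasta(config.source_tg_fasta, "nucleotide")
        self.target_seqs = read_fasta(config.target_fasta, "nucleotide")
        self.promoters = (
            read_fasta(config.promoter_fasta, "nucleotide")
            if config.promoter_fasta else []
        )
        self.motifs = read_motif_table(config.motif_table)
        self.network = read_network(config.network_table)
        self.source_annotations = (
            read_annotations(config.source_annotations)
            if config.source_annotations else {}
        )
        self.target_annotations = (
            read_annotations(config.target_annotations)
            if config.target_annotations else {}
        )
        self.expression = (
            read_expression_matrix(config.expression_table)
            if config.expression_table else None
        )


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute the full pipeline from files, writing artifacts and manifest."""
    scenario = _FileScenario(config)
    if config.tg_mode in ("pr", "galf") and not scenario.promoters:
        raise ValueError(f"tg_mode {config.tg_mode!r} needs promoter_fasta")
    discovered = (
        read_motif_table(config.discovered_motif_table)
        if config.discovered_motif_table else None
    )
    if scenario.expression is None:
        raise ValueError("expression_table is required to confirm links")
    run = run_scenario(
        scenario,
        tf_mode=config.tf_mode,
        tg_mode=config.tg_mode,
        min_score_tf=config.min_score_tf,
        min_score_tg=config.min_score_tg,
        max_evalue=config.max_evalue,
        strands=config.strands,
        tier_config=TierConfig(
            contradictory_weight=config.contradictory_weight,
            neutral_weight=config.neutral_weight,
        ),
        discovered_motifs=discovered,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_similarity_table(run.tf_hits, out / "tf_hits.tsv")
    write_similarity_table(run.tg_hits, out / "tg_hits.tsv")
    _write_tf_map(run.tf_map, out / "tf_map.tsv")
    _write_tg_map(run.tg_map, out / "tg_map.tsv")
    _write_links(run.integration, out / "links.tsv")
    run.report.per_link.to_csv(out / "confirmation.tsv", sep="\t", index=False)
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(run.manifest(), sort_keys=True), encoding="utf-8"
    )
    return run


def _write_tf_map(tf_map, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#source_tf_id\ttarget_seq_id\tmode\n")
        for source, target in sorted(tf_map.pairs):
            fh.write(f"{source}\t{target}\t{tf_map.label}\n")


def _write_tg_map(tg_map, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#source_tg_id\ttarget_seq_id\tmatched_motif_ids\tmode\n")
        for source, target, motif_ids in sorted(
            tg_map.entries, key=lambda e: (e[0] or "-", e[1])
        ):
            joined = ",".join(sorted(motif_ids)) if motif_ids else "-"
            fh.write(f"{source or '-'}\t{target}\t{joined}\t{tg_map.label}\n")


def _write_links(integration: IntegrationResult, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "#source_tf\tsource_tg\ttarget_tf\ttarget_tg\tsign\t"
            "supporting_motifs\tprovenance\n"
        )
        for link in integration.links:
            fh.write(
                "\t".join(
                    [
                        link.source_tf_id, link.source_tg_id,
                        link.target_tf_id, link.target_tg_id,
                        link.sign.symbol,
                        ",".join(sorted(link.supporting_motif_ids)),
                        link.provenance,
                    ]
                )
                + "\n"
            )
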