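# reglinkmap

Map a transcriptional gene-regulatory network from a model (source) organism
to a non-model (target) organism, and grade the transferred links against the
little expression data a non-model organism typically has.

Experimentally determined regulatory networks — signed TF → target-gene (TG)
edges, positive for activation and negative for repression — exist for only a
handful of model organisms. For a newly sequenced genome with nothing but
nucleotide sequence data, `reglinkmap` transfers links in three steps:

1. **TF mapping.** Source TFs are matched to target sequences by local
   sequence similarity, optionally refined by requiring the pair to share a
   protein family (`TFf`) or subfamily (`TFsf`) label from a
   PANTHER/InterProScan-style annotation table. The unrefined similarity set
   is `TFbl`.
2. **TG mapping.** Candidate target genes come from sequence similarity
   (`TGbl`), from scanning IUPAC consensus binding-site motifs over gene
   sequences (`TGbs`) or promoters (`TGpr`, `TGgalf` for an externally
   discovered motif set), or from both (`TGblbs`: similar sequences that also
   carry a motif of the source TG's regulator).
3. **Link integration.** For each source link TF → TG, the TF's motifs found
   in the source TG are searched in the candidate target genes; every
   (mapped TF, motif-carrying candidate) pair becomes a predicted link with
   the inherited sign.

Predicted links are then confirmed against a gene × experiment matrix of
ternary expression calls (expressed `Y` / not expressed `N` / absent `ab`).
Each experiment is Confirming, Contradictory, Neutral, or ignored — e.g. an
activation link is confirmed by co-expression and contradicted when the TF is
expressed but the TG is not; a repression link is confirmed by discordant
calls. Per link, the Confirming count *c* is compared against the weighted
sum 2·Contradictory + 1·Neutral (a link with *c* strictly above it is
**verified**) and against 3× / 2× / 1× the Contradictory count, giving four
ratio tiers. Mapping-set quality is evaluated as a binary classifier
(TP/FP/TN/FN, sensitivity TP/(TP+FN), PPV TP/(TP+FP)) against a gold-standard
list within an explicit sequence universe.

A synthetic-scenario generator (`reglinkmap.synthetic_data`) builds complete
paired source/target data sets — homologs under a substitution model, planted
motif instances, nested annotations, calibrated expression matrices — with a
known truth table, so the whole pipeline is testable without downloads.

## Worked example

Generate a scenario (10 source TFs, 50 TGs, 2 motifs per TF, 80% of TFs and
TGs conserved at 5% substitution, 60% of eligible links conserved, a
43-experiment expression matrix) and run the strictest combination,
subfamily-refined TFs with similarity-plus-motif TGs:

```
$ reglinkmap simulate --seed 4 --out-dir fixtures
$ reglinkmap run --config config.yaml        # paths + tf_mode: sf, tg_mode: blbs
{
  "version": "0.1.0",
  "provenance": "TFsf-TGblbs",
  "n_mapped_tf_pairs": 8,
  "n_mapped_tfs": 8,
  "n_mapped_tg_entries": 22,
  "n_mapped_tgs": 22,
  "n_source_links": 50,
  "n_source_links_without_motif": 0,
  "n_links_mapped": 22,
  "links": 22,
  "links_analyzed": 22,
  "links_verified": 22,
  "strong_3x": 22,
  "strong_2x": 0,
  "weak": 0,
  "unsupported": 0
}
```

Reading: 8 of 10 source TFs found a subfamily-concordant homolog (the other
2 were not conserved in this draw); 22 source TGs survived the
similarity-plus-motif filter; the 50 source links collapse onto 22 predicted
target links, every one analyzed (≥ 1 informative experiment) and verified
(*c* > 2·Contradictory + Neutral) because the generator plants Confirming
patterns at rate 0.8 for true links. On real data the verified fraction is
the headline number: the share of transferred links the expression compendium
actually supports. Per-stage artifacts (`tf_map.tsv`, `tg_map.tsv`,
`links.tsv`, `confirmation.tsv`, `manifest.yaml`) land in the output
directory; every stage is also available as its own subcommand (`hits`,
`scan`, `map-tf`, `map-tg`, `integrate`, `confirm`, `evaluate`, `compare`)
and as plain library functions.

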