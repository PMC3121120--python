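# Methods

## The mapping procedure and its assumptions

`reglinkmap` transfers a signed regulatory network TF → TG between genomes
under three biological assumptions: (i) sequence similarity preserves
function well enough that a local-alignment hit is a candidate ortholog;
(ii) a TF's binding specificity — written as a set of IUPAC consensus
motifs — is conserved, so a transferred link is only plausible when a motif
the TF actually uses in the source TG also occurs in the candidate target
gene; (iii) the *type* of regulation (activation/repression) carries over
unchanged, so the predicted link inherits the source sign. Only direct
transcriptional links are modelled: indirect regulation through feed-forward
chains, post-transcriptional control, and binding-site accessibility
(nucleosome occupancy) are out of scope, and the expression-based
confirmation step exists precisely because assumptions (i)–(iii) fail for an
unknown fraction of links.

TF mapping is a nested chain of filters: `TFbl` (similarity only) ⊇ `TFf`
(plus shared protein family) ⊇ `TFsf` (plus shared subfamily). Family labels
are **inputs** (a TSV exported from a PANTHER-style scan); refinement is a
concordance test between the source TF's label and the candidate's label,
and a pair missing a label on either side is dropped — refinement demands
positive evidence. TG mapping produces `TGbl`, `TGbs`, `TGblbs`, `TGpr`,
`TGgalf`; the three motif-only sets are one computation over different
databases/motif provenances and carry no source-gene association. At
integration, similarity-based TG sets restrict candidates to targets mapped
from the link's own source TG, while motif-only sets pair a link with *any*
motif-carrying entry — the combinatorial cost of dropping the homology
constraint is intentional and visible in the link counts.

## Expression confirmation

Calls are ternary per gene and experiment. For an activation link,
(Y,Y) confirms, (Y,N) contradicts, (N,Y) is neutral (the TG may have other
activators), (N,N) is uninformative; for a repression link the discordant
patterns confirm and the concordant ones — including (N,N) — contradict,
so repression admits no neutral outcome. Any absent call ignores the
experiment. Two gradings are computed independently per link from the counts
(c, contradictory, neutral):

* **verified** — `c > w_x·contradictory + w_n·neutral`, strict inequality,
  default weights `w_x = 2`, `w_n = 1`. The weighting demands that
  confirmations outweigh contradictions doubly and neutral observations
  singly, damping single-experiment outliers.
* **ratio tier** — `c ≥ 3·contradictory` (strong), `≥ 2·` (moderate),
  `≥ 1·` (weak), else unsupported; lower bounds inclusive, upper bounds
  strict. A link with no informative experiment at all is `no_data` and does
  not count as analyzed. The four tiers partition the analyzed links; the
  boundaries and weights are exposed in `TierConfig` because reasonable
  conventions differ at the edges (e.g. `c = contradictory = 0` with only
  neutral evidence lands in the strong tier under these rules).

Genes missing from the expression matrix behave as absent in every
experiment — links touching them are simply never analyzed rather than
erroring, which is the weakest assumption that keeps the report total.

## Similarity computation

The built-in aligner (exact optimal local alignment, match +1, mismatch −1,
linear gap −2, via `Bio.Align.PairwiseAligner`) exists so the pipeline runs
at desk scale; for genome-scale work, bring precomputed hits in the
12-column BLAST-tabular dialect instead. The reported e-value for internal
hits is the monotone surrogate `exp(−score)`: it ranks consistently within a
run but is not database-size corrected, so e-value filtering of internal
hits is equivalent to score filtering (default cut-off 1e−5, a conventional
stringent choice; prior cross-genome mapping work shows the threshold choice
matters more than the aligner). Alignment spans and identity are taken from
the aligner's first reported optimal traceback — deterministic for fixed
inputs, though ties between co-optimal tracebacks are broken by the
aligner's internal order rather than a coordinate rule; only the score
(exact) is consumed downstream. Linear rather than affine gap costs keep the
oracle contract simple; affine costs are a straightforward extension point.
The default `min_score` used by the pipeline helper is half the median query
length: far above the logarithmic background score of unrelated sequences
under +1/−1 scoring, far below the ≈ 0.9·length score of a 5%-diverged
homolog.

## Motif scanning

Motifs are IUPAC consensus strings, not weight matrices (the consensus form
is what curated TF-motif collections provide; PWMs are an extension point).
Matching uses subset semantics: a sequence letter matches a motif letter iff
its base set is contained in the motif letter's set, so `N`-runs in draft
genomes match only an all-permissive motif position instead of everything.
Both strands are scanned by default (binding sites are double-stranded
features); minus-strand hits are reported in forward coordinates (0-based,
half-open). All overlapping occurrences are reported, but every downstream
consumer uses presence/absence only, so overlap policy cannot change
results. When promoter sequences are unavailable, whole gene sequences are
scanned; restricting to an upstream window is input preparation, not scanner
logic.

## The scenario generator

`generate_scenario` emulates: source TF/TG sequences; per-TF concrete motifs
(pairwise distinct, including reverse complements); a signed network
(default 10 TFs × 5 TGs each over 50 TGs, 70% activation, chosen so each TG
has a single regulator — which keeps the expression calibration exact);
target homologs mutated at a per-base substitution rate (default 5%, no
indels); decoy sequences; nested annotations (conserved homologs share
family and subfamily, 20% of decoys get a right family with a wrong
subfamily); promoters; and a 43-experiment ternary expression matrix.

Two construction guarantees make the truth table exact rather than merely
likely. First, a conserved link's motif instance is re-planted intact in the
target homolog and its promoter. Second, every *other* motif occurrence —
chance matches in background sequence, and planted instances surviving
mutation in non-conserved targets (an 8-mer survives 5% per-base mutation
with probability ≈ 0.66, which would otherwise leak non-conserved links into
the predictions) — is knocked out by point mutations outside protected
windows, iterating until a rescan is clean. Expression is calibrated by a
latent per-TF call (P(expressed) = p_confirm + p_contradict) with the TG
call drawn conditionally, so each activation link's Confirming probability
is exactly `p_confirm_true` (default 0.8) per experiment despite one TF
sharing its call across its links; repression links have no neutral cell,
so their informative mass splits Confirming:Contradictory in proportion
p_confirm:p_contradict. `p_absent` (default 0.05) applies per gene per
experiment; undriven genes are expressed with probability one half, making
decoy links' Confirming and Contradictory counts symmetric in expectation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels, duplications and rearrangements; codon
structure and GC heterogeneity; motif degeneracy and turnover (real sites
drift, planted ones are exact); shared regulators per TG at default
settings; correlated experiments or time-course structure; and the
genome-scale ratio of decoys to true sequences. Recovery rates on scenarios
are therefore construction checks, not performance claims.

## Numerical and design choices

* All randomness flows through one `numpy.random.default_rng(seed)`; byte
  reproducibility holds per installed environment, and the generator's
  algorithm and seed are recorded in the bundle manifest.
* Writers sort by primary id and emit Unix newlines; readers preserve file
  order. TSV headers are `#`-prefixed; FASTA is left header-free because a
  `#` line would break standard parsers.
* Hit-table coordinates are 1-based inclusive (tabular-dialect convention);
  all motif coordinates are 0-based half-open.
* Numeric expression mode calls a gene expressed at value ≥ threshold
  (inclusive boundary).
* Duplicate predicted links onto one (target TF, target TG, sign) are
  collapsed with motif sets unioned and the lexicographically smallest
  source pair retained.
* "Links analyzed" counts links with at least one informative experiment —
  the weakest condition under which any confirmation rule can fire.
* Degenerate inputs: empty query sets yield empty results; a source link
  whose TG carries none of its TF's motifs is skipped and counted
  (`n_skipped_no_motif`); undefined sensitivity/PPV are reported as
  `None`, never 0.
* Scenario sizes in the test suite and acceptance script (tens of genes,
  hundreds of bases) are the package's desk-scale design point; every
  algorithm is size-agnostic.

## Known limitations

Besides the modelling scope above: the internal aligner is O(nm) per pair
with no heuristic seeding, so all-vs-all search beyond a few hundred
sequences belongs to an external tool; surrogate e-values are not comparable
across runs; motif discovery (for the `TGgalf` provenance) is not
implemented — the discovered motif set is an input; and confirmation treats
experiments as exchangeable, ignoring any dependence structure in the
compendium.
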