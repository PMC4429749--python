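# Methods

This note documents the models and procedures implemented in
`mirregnet`, the assumptions behind them, the defaults that matter, and
what the synthetic benchmark does and does not demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open internally. BED and bedGraph are
native to this convention; GFF3 (1-based closed) is converted on read
and write. Overlapping bedGraph records are **summed**, i.e. treated as
coverage contributions rather than last-wins assignments. Signal tracks
are dense per-base arrays per sequence; windowed statistics use cached
prefix sums, so scanning many candidate positions costs O(bins) each.

Organellar sequences are excluded from classifier training via a
configurable seqid blacklist defaulting to `{ChrC, ChrM, Pt, Mt}`:
chloroplast and mitochondrion lack the TSS-tag/ChIP evidence the model
relies on, and the rule is expressed as identifiers because annotation
sources differ in naming.

The "upstream" of a locus is strand-aware: upstream of a minus-strand
precursor lies at higher coordinates, and promoter sequences extracted
for minus-strand TSSs are reverse-complemented so they always read
5'→3' toward the TSS. Windows are clipped, not errors, at contig
boundaries (only a fully empty window raises).

## Feature extraction

A candidate position is described by per-feature binned counts in a
±`span` window: track features sum per-base coverage per bin, motif
features count site starts per bin, and both use half-open bins with
the boundary site assigned downstream. Minus-strand windows reflect
positions around the anchor (rel = anchor − p with the same half-open
binning) before mirroring the bin order; this makes plus/minus profiles
of a strand-symmetric signal *identical*, not merely close.

Defaults: classifier window ±1000 bp at 200-bp bins (10 bins/feature,
9 features → 90 values); meta-profiles (the diagnostic "enrichment
around TSSs" view) use ±5 kb at 200-bp bins. The bin statistic is the
sum, matching the accumulative-count reading of such profiles. Features
are concatenated in alphabetical order so the layout is independent of
configuration order; the layout travels with the trained model and is
checked at prediction time.

## TSS classifier

* **Positives.** Verified TSSs of protein-coding genes, restricted to
  genes with exactly one recorded TSS (multi-TSS genes are dropped
  entirely — a gene with ambiguous starts is not a clean label).
* **Negatives.** Uniform random genomic positions at least 1 kb from
  every recorded TSS (and from any other anchor the caller declares,
  e.g. known miRNA TSSs), matched 1:1 to the positives and sampled
  without replacement, reproducibly per seed. Random distance-matched
  background is the conventional choice where no curated non-promoter
  set exists; the distance and ratio are configurable.
* **Model.** Soft-margin SVM, RBF kernel, C = 1, γ = 1/n_features,
  on per-feature z-scaled inputs (scaling fitted on the training set
  and stored in the model file). Any classifier exposing a decision
  score could be substituted; the SVM's decision function is stored
  explicitly (support vectors, dual coefficients, intercept, γ), so a
  saved model is a plain zip of JSON metadata plus `.npy` blobs and
  predicts without refitting. Saved archives use fixed zip timestamps
  and are byte-reproducible.
* **Validation.** Stratified 5-fold cross-validation reporting
  sensitivity, specificity, precision and accuracy per fold and as the
  fold mean. Samples are put into a canonical order before fold
  assignment, so permuting the input does not move samples between
  folds. The identity accuracy = (sens·P + spec·N)/(P+N) is asserted
  on every fold. Feature-combination selection evaluates arbitrary
  candidate subsets and returns the accuracy-maximising set, ties
  broken toward fewer features then lexicographically, with the full
  table returned for inspection.
* **Scanning.** Every 20th position of the 10-kb upstream window is
  scored; non-maximum suppression with a 200-bp exclusion radius keeps
  local peaks; at most 10 candidates are ranked by decreasing score,
  ties broken toward the position nearer the precursor 5' end (a
  proximal-promoter prior). The 20-bp step and 200-bp radius trade
  resolution against cost: the feature bins are 200 bp wide, so a finer
  step adds little. Intragenic precursors take their host gene's TSS as
  rank 1 without scanning. EST and conservation evidence, where
  supplied, are report-only overlays (boolean overlap with a candidate
  ±100 bp), not classifier features — they are corroborating
  annotations of a different character than the training tracks.

## Coexpression

Expression matrices are entities × conditions; the two matrices being
correlated must share the condition axis exactly (aligning heterogeneous
condition sets is upstream curation, not something the package guesses
at). Normalisation options: per-entity z-score (population sd,
zero-variance entities excluded), quantile (columns forced to the mean
sorted distribution, ties mid-ranked), or division by an internal
control gene per condition. Correlation is Pearson (default) or
Spearman (Pearson on mid-ranks). A miRNA's coexpression group is all
genes with |r| ≥ 0.9, sign retained — co-regulation can be activating
or repressive, and downstream filters can restrict the sign. Groups
smaller than `min_genes` = 10 are relaxed to the top-10 by |r| and
flagged: the over-representation statistic degenerates on tiny groups.
miRNAs without expression profiles are skipped.

## Match-style PWM scanning and the coTFBS statistic

PWM rows are normalised frequencies; zero frequencies are legal because
the information weight defines 0·ln 0 = 0 and nothing else takes logs
of frequencies (a pseudocount is available but off by default). The
matrix similarity score (MSS) is the information-weighted per-position
frequency of the observed bases, min-max normalised to [0, 1]; the core
similarity (CSS) applies the same formula to the 5 consecutive
positions with maximal summed information (leftmost on ties; matrices
shorter than 5 fall back to full length with a warning). Ambiguous
bases contribute the position's minimum frequency — the conservative
reading. A zero-information matrix scores 0 with a warning rather than
0/0. Both strands are scanned; minus-strand hits are reported at the
forward-strand offset of the site's leftmost base. Hit thresholds
default to CSS ≥ 0.75 and MSS ≥ 0.85, a false-positive-averse profile;
both are configurable.

The coTFBS statistic uses **promoter-presence counts**: each
(promoter, PWM) pair contributes at most one detection, making the
hypergeometric urn draws exchangeable and guaranteeing k ≤ n. With N
all detections across every coexpressed group in the run, K detections
of one PWM across groups, n detections inside the focal group and k of
them this PWM, the reported p-value is the upper tail P(X ≥ k) — the
point mass alone does not measure over-representation, though it is
available (`tail="point"`). The group's promoters include the miRNA's
own promoter (the statistic asks about sites shared by the miRNA and
its coexpressed genes); a flag excludes it. TF candidates must pass
frequency > 0.5 *strictly* and p < 0.1 *strictly*, sorted by p then
frequency then id. At least two groups are required — the background is
"all groups in the run". Evaluation is in log space via the standard
library routines, and tests pin both tails to an exact
rational-arithmetic oracle.

## Targets, DFS expansion, GO enrichment, network

Gene–gene edges are directed regulator→regulatee; undirected input is
expanded to both directions on request. Indirect targets are every gene
reachable from a direct target, found by an explicit depth-first
search that visits each node once (so feedback loops and self-edges
terminate), with deterministic traversal: roots and children in
lexicographic order. The result is a spanning forest with per-node
depth; expansion depth is unbounded by default. Equivalence with
boolean-matrix transitive closure is asserted on random digraphs.

GO enrichment reuses the same upper-tail hypergeometric on
(background, term, query) counts; the background defaults to all
annotated genes, terms smaller than 2 genes are skipped, and
Benjamini–Hochberg adjustment is optional and off by default (the raw
hypergeometric p is the primary statistic). Ancestor propagation of GO
terms is the caller's responsibility.

Duplicate miRNA–target records merge with "verified" evidence
dominating "putative" and sources concatenated. The assembled network
is a typed `networkx.DiGraph` (TF, miRNA, direct_target,
indirect_target nodes; regulates/targets/interacts edges carrying their
statistics, evidence and correlations), exportable as SIF, GraphML
(round-trips exactly) and Cytoscape JSON.

## Synthetic data: what it emulates, and what it does not

The generator plants recoverable instances of every signal the pipeline
detects. Defaults: 2 chromosomes × 300 kb of uniform-composition
sequence, 20 miRNA precursors (15% intragenic), 500 expression-profiled
genes over 11 conditions. Precursors occupy 22-kb tiles so that each
10-kb upstream scan window contains exactly one planted TSS and no
other planted bump — the recovery benchmark measures the scanner, not
collisions of the layout. About 40 of the 500 genes receive genomic
loci and TSSs in separate gene zones (4-kb spacing); these train the
classifier. Packing all 500 into 600 kb would leave no position ≥ 1 kb
from a TSS for negative sampling and would fill the scan windows with
extraneous true signal, so the rest of the pool exists as expression
entities, coexpression-block members, targets and graph nodes only.

Coverage is Poisson-sampled around deterministic shapes — Gaussian
bumps at every true TSS for TSS tags (height 40, sd 25 bp) and
H3K4me3/H3K9ac (height 25, sd 150 bp), and a baseline-8 H3 track with a
depth-6 Gaussian dip floored at zero — mimicking read-count noise.
Motif sites appear at an elevated rate within ±100 bp of TSSs and at
background rate elsewhere. Expression: each miRNA has a latent
standard-normal condition profile; its block of 20 coexpressed genes
adds N(0, 0.1) noise to it, planted targets get the negated profile
plus N(0, 0.05), all other genes are independent. Planted TF consensus
sites go into 80% of a group's promoters, 10% of other groups'
(cross-talk), with decoy PWMs inserted uniformly at 30% — common enough
to be detected but carrying no group-specific signal, so they exercise
the frequency and p filters separately. The gene graph is Erdős–Rényi
(density 0.05) plus one guaranteed 3-gene chain per direct target; one
GO term annotates 90% of the focal miRNA's mediated gene set against
20 background terms at 5% annotation rate.

All stages draw from per-stage generators spawned from (seed, stage)
pairs, and every emitted file is byte-identical across runs of the same
configuration.

**Limitations.** The background sequence is i.i.d. uniform — no GC
skew, repeats, or compositional structure that inflates motif false
positives in real genomes; coverage noise is pure Poisson with no
mappability or library-size artefacts; expression noise is Gaussian
without batch structure; the condition axis of miRNA and gene matrices
is shared by construction, sidestepping the cross-platform alignment a
real analysis must do. Passing the recovery benchmarks therefore shows
the machinery is correct and sensitive under its stated model, not that
the defaults transfer to any particular real dataset — thresholds,
window sizes and normalisation all remain knobs the user must justify
on real inputs.

## Numerical choices and degenerate inputs

* Hypergeometric and correlation statistics delegate to the standard
  scientific routines; exactness is pinned by rational-arithmetic and
  two-pass oracles in the test suite (≤ 1e−12 absolute).
* z-scoring uses the population sd; zero-variance entities are excluded
  with a warning rather than propagating NaNs.
* Equal scan scores break toward the precursor-proximal position;
  equal feature-selection accuracies break toward smaller sets;
  equal core-information windows break leftmost.
* Empty upstream windows, empty coexpression groups, missing expression
  for an MTI and an empty exported network are warnings or flagged
  values, not errors — they are expected states of sparse real data.
  Inconsistent count tuples, condition-axis mismatches and feature
  layout mismatches are hard errors — they indicate upstream bugs.

## Benchmark sizes

The default test and acceptance runs use the generator defaults above
(80 training anchors, 20 scan windows of 10 kb at 20-bp steps, six
PWMs over ~60 kb of promoter sequence per simulation, 20 independent
simulations for the TF/GO recovery rates). These sizes keep every
planted structure comfortably recoverable while the full suite runs in
well under a minute of compute per simulation batch.
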