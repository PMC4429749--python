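# mirregnet

Reconstruction of plant miRNA regulatory networks: promoter/TSS
prediction from chromatin evidence, transcription-factor inference from
shared binding sites in coexpressed-gene promoters, and target-circuit
expansion into a typed, exportable network.

## The problem

Plant miRNAs are mostly intergenic, Pol II-transcribed genes with their
own promoters, yet for the vast majority the transcription start site
(TSS) — and hence the promoter, and hence the regulating transcription
factors — is unknown. `mirregnet` implements a complete method stack
for *Arabidopsis*-style genomes:

1. **TSS prediction.** Around genuine TSSs, TSS tags (5' ends of
   full-length cDNAs), H3K4me3 and H3K9ac are enriched while nucleosome
   H3 coverage is depleted, and five core-promoter motif classes
   (Y patch, Inr, CA, GA, REG) cluster. Each candidate position is
   summarised as binned counts of these nine features in a ±1 kb window
   and classified by a soft-margin SVM (RBF kernel) trained on verified
   protein-coding-gene TSSs (unique-TSS genes only, organelles
   excluded) versus distance-matched random genomic background. The
   trained model scans the 10-kb region upstream of each pre-miRNA,
   non-maximum suppression thins the scores, and up to ten ranked
   candidates are reported — rank 1 is the representative TSS.
   Intragenic precursors (same strand, inside an annotated gene)
   instead inherit their host gene's TSS.
2. **TF → miRNA inference (coTFBS).** Genes coexpressed with a miRNA
   (|r| ≥ threshold, Pearson or Spearman) form a group; promoters of
   the group and of the miRNA are scanned with PWMs using Match-style
   information-weighted scores

   MSS = (Current − Min)/(Max − Min),  Current = Σᵢ I(i)·f(i, bᵢ),
   I(i) = Σ_b f(i,b)·ln(4 f(i,b)),

   with a core score (CSS) over the five most informative consecutive
   positions. A TFBS present in most of a group's promoters
   (frequency > 50%) and over-represented relative to all groups by an
   upper-tail hypergeometric test,

   P(X ≥ k) = Σ_{j≥k} C(K,j)·C(N−K, n−j) / C(N,n),   p < 0.1,

   nominates its TF as a regulator of the miRNA.
3. **Targets and networks.** miRNA–target interactions (verified or
   putative) are annotated with the expression correlation between
   miRNA and target; depth-first search through directed gene–gene
   interaction edges expands each direct target into its downstream
   circuit (the indirect targets), terminating on cycles and
   self-edges; GO-term enrichment of the mediated gene set uses the
   same hypergeometric statistic. TF→miRNA, miRNA→target and gene→gene
   layers assemble into a typed directed graph exportable as SIF,
   GraphML or Cytoscape JSON.

A fully deterministic synthetic-data generator
(`mirregnet.simulate`) emits every input format the pipeline reads —
genome FASTA, GFF3, TSS BED, bedGraph coverage, motif BED, expression
TSV, JASPAR PWMs, MTI/edge/GO tables — with planted ground truth, so
the whole stack is testable offline.

## Worked example

```python
from mirregnet.simulate import SimulationConfig, simulate_all
from mirregnet import tss

sim = simulate_all(SimulationConfig(seed=1))
training = tss.build_training_set(
    sim.tss_records, sim.tracks, sim.motifs, sim.genome_lengths, seed=1,
    extra_avoid=[(s, p) for s, p, _ in sim.truth.true_tss.values()])
metrics = tss.cross_validate(training, n_folds=5, seed=1)
print(f"5-fold CV: accuracy={metrics.accuracy:.3f} "
      f"sensitivity={metrics.sensitivity:.3f} "
      f"specificity={metrics.specificity:.3f} "
      f"precision={metrics.precision:.3f}")

model = tss.train(training, seed=1)
host = {r.gene_id: r for r in sim.tss_records}
cands = tss.predict_mirna_tss(model, sim.mirnas, sim.tracks, sim.motifs,
                              sim.genome_lengths, host_tss=host)
truth = sim.truth.true_tss["ath-MIRsim002"]
print(f"planted TSS at {truth[0]}:{truth[1]} ({truth[2]})")
for c in cands["ath-MIRsim002"][:3]:
    print(f"  rank {c.rank}: {c.position.seqid}:{c.position.start} "
          f"score={c.score:.2f}")
```

prints

```
5-fold CV: accuracy=0.975 sensitivity=1.000 specificity=0.950 precision=0.960
planted TSS at Chr1:38549 (-)
  rank 1: Chr1:38560 score=1.24
  rank 2: Chr1:37520 score=0.05
  rank 3: Chr1:37740 score=0.05
```

The classifier separates planted TSS chromatin from background at 97.5%
cross-validated accuracy, and the rank-1 candidate lands 11 bp from the
planted TSS (scan resolution is 20 bp); lower-ranked candidates sit at
background score levels. The TF layer behaves the same way — for the
first simulated miRNA's coexpression group the only candidate passing
the frequency > 0.5 and p < 0.1 filter is the planted factor:

```
TF1: frequency=0.81 p=6.74e-06 (N=120, K=24, n=37, k=17)
```

Here k of the group's n promoter–PWM detections are this TFBS, against
K of N across all groups.

The same pipeline is available from the shell:

```
mirregnet run-all --seed 1 --out run/
```

which simulates a dataset, trains and applies the TSS model, forms
coexpression groups, ranks TF candidates, expands targets, tests GO
enrichment, exports the network (`network.sif`) and writes a
`manifest.json` of output checksums.

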