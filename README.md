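# gocentric

GO-centric interpretation of time-course RNA-seq counts.

Conventional analysis of a transcriptome time course clusters the
differentially expressed genes (DEGs) by expression pattern and then
annotates each cluster with Gene Ontology (GO) enrichment.  That order
has two failure modes: genes that change *gradually* never clear a
fold-change cutoff between neighbouring time points and are missed, and
a functional category whose members move in *opposite* directions is
scattered across clusters, diluted by unrelated genes, and overlooked by
per-cluster enrichment.  `gocentric` inverts the order:

1. **pan-DEGs** — test every pair of time points (all C(T,2)
   comparisons, not just consecutive ones) with a negative-binomial
   exact test and take the non-redundant union of the calls;
2. **GO enrichment** of the pan-DEG set (classic Fisher and the elim
   algorithm on the true-path-propagated ontology);
3. **GO-centric clustering** — hierarchically cluster the genes of each
   enriched term into expression subclusters;
4. **motif contrast** — test the promoters of the two largest
   subclusters for TFBS motif enrichment against background promoters.

The package targets bulk RNA-seq time courses (the reference design is
4 time points × 3 replicates) starting from a gene × sample counts
matrix.  A synthetic-data generator with planted ground truth (DEG
patterns, a deliberately diluted GO module, promoter motifs) makes every
stage testable without any external download.

## Model summary

Counts follow NB(μ, φ) with Var = μ + φμ².  After TMM normalisation and
rescaling to a common effective library size, replicate counts are
summed per group and the group-A sum is compared to the total with the
conditional exact test (binomial in the Poisson limit φ = 0); two-sided
p-values use the minimum-likelihood rule.  Dispersion is estimated by
conditional likelihood with shrinkage toward the common value.  A gene
is a DEG when the Benjamini–Hochberg adjusted p ≤ 0.01 and
|log2FC| > 1.  Enrichment p-values are one-sided hypergeometric;
clustering uses d = 1 − Pearson r with silhouette-selected K (5–10) for
the k-means baseline and average linkage for the GO-centric dendrograms;
motif enrichment is ZOOPS-counted hypergeometric over log-odds PWM hits
at 80% of the maximum score.  Details and rationale: `docs/methods.md`.

## Worked example

Generate the default synthetic study and run the whole pipeline:

```sh
gocentric --seed 1 simulate --outdir demo
gocentric --seed 1 run --indir demo --outdir demo_out
```

or, in Python:

```python
import gocentric as g
from gocentric.pipeline import RunConfig, run_pipeline
from gocentric.synthetic import write_scenario

scenario = g.default_scenario(seed=1)
paths = write_scenario(scenario, "demo")
cfg = RunConfig(seed=1)
cfg.counts, cfg.meta = str(paths["counts"]), str(paths["meta"])
cfg.obo, cfg.annotations = str(paths["obo"]), str(paths["annotations"])
cfg.fasta, cfg.bed, cfg.jaspar = str(paths["fasta"]), str(paths["bed"]), str(paths["jaspar"])
res = run_pipeline(cfg, "demo_out")
```

The per-comparison DEG counts show the pan-DEG rationale — the skip
comparisons (e.g. 24h vs 72h) call many genes the consecutive
comparisons miss:

```
comparison  up  down
 0h_vs_24h 151   152
 0h_vs_48h 161   155
 0h_vs_72h 160   161
24h_vs_48h  12    13
24h_vs_72h 107    70
48h_vs_72h   1     0
pan-DEG union: 346
```

GO enrichment of the 346 pan-DEGs puts the planted module first —
40 of its 40 genes are differential:

```
      term                             name  annotated  significant    p_classic
GO:1000001 diluted opposite-response module         40           40 2.164234e-31
GO:0000009              synthetic process 9        103           47 2.187444e-11
...
```

Yet in the conventional baseline (silhouette chooses K = 5) the same
term is not significant in *any* k-means cluster (its smallest
per-cluster p is ≈ 0.15): its 20 induced and 20 repressed genes sit in
opposite pattern clusters, each diluted by ~130 unrelated genes.  The
GO-centric dendrogram of the term recovers exactly those two groups as
the top two subclusters (sizes 20/20), and their promoters show the
planted motif contrast:

```
subcluster 1 top motif:
         motif  targets_with_hit  n_targets  background_with_hit  n_background   fold            p
  SYN_UP_MOTIF                18         20                  107          1906  13.87 2.129221e-20
subcluster 2 top motif:
SYN_DOWN_MOTIF                15         20                  127          1906  10.17 5.704900e-14
```

The sample dendrogram confirms replicate reproducibility — every time
point's three replicates form a clade:

```
monophyly: {'0h': True, '24h': True, '48h': True, '72h': True}
```

`demo_out/` contains one directory per stage (normalisation factors,
per-comparison DE tables, pan-DEG provenance, enrichment tables, cluster
assignments, per-term Newick dendrograms and motif tables) plus a
`config.json` snapshot sufficient to reproduce the run.

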