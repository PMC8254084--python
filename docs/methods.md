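# Methods

`gocentric` implements a GO-centric strategy for interpreting time-course
RNA-seq: instead of clustering differential genes first and annotating
clusters afterwards, it first assembles an exhaustive ("pan") set of
differentially expressed genes (DEGs), runs GO enrichment on that set,
and only then clusters the genes of each enriched term into expression
subclusters, whose promoters are finally contrasted for TFBS motifs.
This note records the statistical model, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate, and
the numerical conventions.

## Differential expression: NB exact test

Counts for gene *g* in library *j* are modelled as negative binomial,
mean μ_gj = λ_g·L_j and dispersion φ_g, so Var = μ + φμ².  The pairwise
test between two time points is the classic conditional exact test:

1. **Filtering.** Genes with a total count below `min_total` (default 10,
   summed over all samples) are removed before anything else.  The
   per-sample alternative is available via a flag; the total-count
   reading is the common idiom for this filter and the default.
2. **Normalisation.** TMM scaling factors (M-trim 0.30, A-trim 0.05,
   inverse-variance weights, geometric mean 1) define effective library
   sizes L_j = N_j·f_j.
3. **Equalisation.** Counts are rescaled to the geometric-mean effective
   library size and rounded to integers, after which replicate counts
   within each group can be summed.
4. **Exact test.** Under the null the group-A sum given the total
   follows the NB-convolution conditional law; its point probabilities
   are enumerated exactly (binomial in the φ = 0 Poisson limit).  The
   two-sided p aggregates all outcomes whose point probability does not
   exceed the observed one (minimum-likelihood rule), capped at 1.  A
   gene with zero total in both groups gets p = 1, log2FC = 0 and a
   `zero_total` flag.
5. **Fold change.** log2FC = log2((s_B/n_B + c) / (s_A/n_A + c)) with a
   prior count c = 0.5 per group to keep zero counts finite, oriented
   later-vs-earlier so a positive sign always means induction over time.
6. **Multiple testing.** Benjamini–Hochberg step-up across genes per
   comparison; a DEG call requires padj ≤ 0.01 **and** |log2FC| > 1
   (both thresholds configurable; padj boundary inclusive, log2FC
   boundary strict).

**Dispersion** is estimated by conditional likelihood on the equalised
counts over a grid (φ = 0 plus 100 log-spaced values in [1e-4, 10]).
The common value maximises the summed conditional log-likelihood; a
per-gene value maximises the gene's own conditional log-likelihood plus
`prior_weight` (default 10, in equivalent genes) times the gene-averaged
likelihood, shrinking unstable per-gene estimates toward the common
value — necessary at n = 3 replicates.  With no replicated group the
estimator refuses and asks for an explicit φ.

## Pan-DEGs

All C(T,2) time-point pairs are tested, each oriented (earlier, later)
in input order.  The pan-DEG set is the union of genes up- or
down-regulated in at least one comparison, with the per-comparison
status kept as provenance (a gene may be up in one comparison and down
in another; both flags are kept).  The motivation is the gradual-drift
failure mode: a gene drifting 0.7 log2 units per step never passes
|log2FC| > 1 between neighbours but exceeds it across two steps, so a
consecutive-only analysis misses it while the skip-level comparisons
catch it.  The generator plants exactly such genes and the acceptance
suite checks the strict set inclusion.

## GO enrichment

The ontology is read from OBO 1.2 (obsolete terms dropped; `is_a`
always followed, `part_of` by default, other relations ignored; cycles
and dangling parents rejected).  Annotations obey the true-path rule:
each gene is propagated to all ancestors of its direct terms.

* **Universe.** All filtered genes carrying at least one propagated
  annotation ("feasible genes"); unannotated genes can be included via
  a flag.  Namespace defaults to `biological_process`; terms with fewer
  than `min_node_size` (default 10) annotated genes in the universe are
  skipped.
* **classic** — one-sided hypergeometric over-representation p per term.
* **elim** — terms visited children-first; when a term's p falls below
  `cutoff` (default 0.01) its propagated genes are removed from every
  ancestor before the ancestor is tested, decorrelating nested terms.
  A cutoff ≥ 1 disables elimination (elim = classic).  Elim p can move
  in either direction relative to classic; only the reduced-table
  recomputation is guaranteed.
* **Ranking** — ascending p, ties by larger annotated count then term
  id; the top 6 terms (configurable) are carried into GO-centric
  clustering.

### Per-cluster enrichment universe

Enrichment of the k-means clusters is computed against the pan-DEG set
itself, not against all expressed genes.  The question asked of a
cluster is "which functions characterise this expression pattern among
all differential genes"; against a whole-transcriptome universe every
DEG-only cluster would trivially over-represent any DEG-dominated term
and the comparison with the pan-DEG-level enrichment would be
meaningless.  The pan-DEG-level enrichment itself uses the full feasible
universe.  Both universes are explicit function arguments, so either
convention can be forced.

## Clustering

Profiles are replicate-averaged log2-CPM (prior 1, effective library
sizes), z-scored per gene (population σ).  A constant profile becomes a
zero vector, is flagged, and has correlation 0 (distance 1) with
everything — this avoids NaN propagation and is documented rather than
hidden.  The distance everywhere is d = 1 − Pearson r ∈ [0, 2].

* **k-means baseline** — on z-scored rows, correlation-distance k-means
  is spherical k-means: assignment by maximum r against centroids,
  centroids re-standardised every iteration, emptied clusters reseeded
  with the farthest point.  Best of 25 seeded restarts by the summed
  within-cluster distance; deterministic given the seed.  K is chosen by
  maximum mean silhouette (precomputed correlation distances) over
  K = 5..10 by default.
* **GO-centric clustering** — average-linkage agglomerative clustering
  (scipy; single/complete/ward available) of one term's genes, cut into
  k = 2 subclusters by default.  Subclusters are renumbered by
  decreasing size; ties break by the height at which the subcluster
  finished forming (lower first), then smallest leaf index.  The two
  largest subclusters are the motif-contrast targets.  "Top two by
  size" was an open choice; size is the only criterion that needs no
  visual judgement.  Dendrograms are exported as Newick.
* **Sample dendrogram** — the same distance over per-library log2-CPM
  vectors; a time point is monophyletic when some internal node contains
  exactly its replicates.  This is the replicate-reproducibility check.

## Motif analysis

Promoters are strand-resolved TSS windows (default 500 bp upstream /
100 bp downstream; compact enough for desk-scale scanning).  On the
plus strand the window is [TSS−up, TSS+down); on the minus strand it is
the reverse complement of [TSS−down, TSS+up) with the TSS at the last
base of the gene interval.  Windows truncated at contig edges are
flagged.  JASPAR count matrices become probability PWMs with a +0.25
pseudocount.  Scanning scores every offset on both strands with
log2(p/background) odds; N contributes 0; a promoter has a motif when
any window reaches 80% of the motif's maximum achievable score (a fixed
score fraction is fully specifiable, unlike p-value-calibrated
thresholds that need an external score distribution).  Enrichment is
ZOOPS (a promoter counts once) with a one-sided hypergeometric test on
the pooled target+background sets; the default background is every
universe promoter outside the target subcluster.  No GC or length
matching is applied — a known limitation: on real genomes, GC-biased
promoter classes can inflate enrichment, and users should supply a
matched background when that matters.

## Synthetic data

The generator emulates the study design the pipeline targets: 4 time
points × 3 replicates, NB counts with common dispersion φ = 0.1,
baselines log-uniform over [20, 2000] plus a 5% near-zero tranche to
exercise the count filter, and library sizes varying ±30% to exercise
TMM.  ~17% of genes get a non-flat pattern, dominated by two opposite
sustained responses ("induced"/"repressed": a 2-log2 step at the second
time point followed by a 0.7-per-step drift) plus minor transient and
gradual classes.  The drift keeps the later time points statistically
separable at the sample level — with a pure step, time points 2–4 would
be identical in expectation and replicate monophyly would be
unattainable by construction — while staying below the |log2FC| > 1
call threshold between neighbours.

The toy GO DAG has one root, three levels of background terms, a
two-parent diamond, and a planted "dilution" module drawn 50/50 from
the induced and repressed patterns: enriched in the pan-DEG set but
spread across opposite expression clusters, it reproduces the pitfall
the GO-centric approach addresses.  The toy genome lays genes on one
contig with random strands and non-overlapping promoter slots and
plants two sharply peaked 8-bp motifs: each in 80% of one module
subcluster's promoters and 5% of the rest.

What the generator does **not** emulate: gene-gene correlation, batch
effects, GC/length bias, varying per-gene dispersion trends
(mean-dispersion relationship), isoform structure, or read-level noise.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under the stated model, not performance on any real
dataset.

## Numerical conventions and problem sizes

* Exact-test tie tolerance: outcomes with point probability within a
  1e-12 relative factor of the observed one count as ties.
* Dispersions below 1e-10 are treated as the Poisson limit to avoid
  overflow of r = 1/φ.
* BH ties resolve by the standard running minimum; output keeps input
  order.
* k-means, dendrogram and subcluster ties break deterministically (leaf
  index / formation height) so repeated runs are byte-identical.
* Test and acceptance problem sizes — 2000 genes for calibration,
  recovery and the end-to-end scenario; 20 null replicates for the
  false-call median; ≤30-element fixtures for the brute-force oracle
  comparisons — were chosen so each stage measures its property at
  stable precision while the whole suite stays desk-scale.

## Known limitations

* The exact test covers two-group comparisons only; no GLM designs,
  quasi-likelihood F-tests, or spline time-course models.
* TMM only (no RLE/upper-quartile); no GC normalisation.
* GO algorithms: classic and elim only (no weight01/parent-child).
* Motif stage: known-motif enrichment only, no de novo discovery, and
  enrichment p-values on real genomes are sensitive to the unmatched
  background noted above.
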