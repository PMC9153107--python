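# Methods

## The classification model

`hyporank` decides whether a single transcriptome (a bulk RNA-seq sample
or one spatial-transcriptomics spot) shows a hypoxic expression program,
without reference samples. The decision is *absolute* because the sample
representation is internal to the sample: every gene is replaced by its
within-sample rank percentile.

### Rank percentiles

For a sample with abundances over *G* genes, genes receive average
competition ranks *r* (smallest value → rank 1; tied values share the mean
of the ranks they cover) and

    percentile = 100 · (r − 1) / (G − 1)

so the most expressed gene scores exactly 100 and the least exactly 0
when those extremes are untied. A tied extreme — most importantly the
block of zero-count genes at the bottom — shares one pooled percentile,
which is deterministic and independent of gene order. Percentiles are
computed over **all** genes of the supplied matrix; restricting to a
signature afterwards never re-ranks, because thresholds learned on
full-transcriptome ranks are only meaningful against full-transcriptome
ranks. A constant column (e.g. a blank spatial spot) gets all-50
percentiles and is flagged rather than fatal, so section-wide runs do not
abort.

Because ranks are invariant under strictly increasing per-sample
transforms, the classifier is unaffected by sequencing depth, CPM/TPM
scaling, or log transforms. It is *not* invariant to non-monotone
per-gene normalizations (e.g. variance-stabilizing residuals); the
package ranks whatever matrix it is given and documents that caveat.

### Decision trees

Trees are induced by greedy recursive partitioning (CART) on percentile
data. At every node the (gene, threshold) pair minimizing the weighted
Gini impurity 1 − p² − (1 − p)² of the two children is chosen by
exhaustive scan, with thresholds placed at midpoints between consecutive
distinct observed percentiles. Samples with percentile exactly equal to a
threshold follow the high branch (the ≥ convention). Split ties are
broken deterministically: lexicographically smallest gene ID, then lowest
threshold. Leaves store the fraction of hypoxic training samples they
contain (the leaf's hypoxia probability), the class label H iff that
probability strictly exceeds 0.5, and the fraction of the training set in
the node.

Default stopping parameters (`TreeTrainParams`): `min_samples_split=20`,
`min_leaf=7`, `max_depth=5`, and a complexity gate that rejects a split
whose total impurity decrease, scaled by the node's share of the training
set, is below `0.01` of the root impurity. These mirror common CART
practice and produce the shallow, human-readable 3–5-gene trees the
method is built around; all are exposed. Forest trees (below) instead
grow essentially to purity (`min_samples_split=2`, `min_leaf=1`, depth
50, no complexity gate), as is standard for bagged ensembles.

The whole induction path is checked against an independent plain-Python
brute-force CART on hundreds of small random instances.

### Feature selection by permutation importance

A random forest (default 200 trees, 10 features considered per split,
bootstrap resampling) ranks candidate genes by **mean decrease in
accuracy** (MDA): per tree, the drop in out-of-bag accuracy when the
gene's values are permuted among that tree's out-of-bag samples, averaged
over all trees of the forest, then over many forests, each grown on a
fresh 70% subsample (without replacement) of the cohort. MDA is reported
**raw**, in accuracy percentage points, not scaled by its dispersion, so
a selection threshold reads directly as accuracy points; 1000 iterations
is the default, and the default selection keeps genes with mean MDA
strictly above 4 points.

Two properties worth remembering when interpreting MDA values:
a gene no tree ever tests has exactly zero importance (permuting an
unused feature cannot change routing), and redundant markers dilute each
other — with 25 partially interchangeable responsive genes, individual
raw MDA values are far smaller than a lone marker's would be. For this
reason an absolute threshold calibrated on one corpus does not transfer
to another; `select_features` therefore also supports a `top_k` cap, and
the end-to-end synthetic emulation selects the top-k genes by MDA rank
rather than applying the absolute default threshold.

Forest hyperparameters can be chosen by `tune_hyperparameters`: mean
holdout accuracy over repeated 70/30 splits for each grid point, ties
going to the smaller model.

### Tree populations and consensus ensembles

`generate_tree_population` trains many candidate trees, each on its own
independent random 70/30 split of the cohort restricted to the selected
genes, and scores each on its own held-out 30%. `filter_by_accuracy`
keeps trees whose holdout accuracy is **strictly** greater than 0.95 (the
"over 0.95" wording is read as strict, as is the "over 50%" probability
rule). `select_top_k_by_f1` narrows to the k trees with the best
unweighted mean F1 across validation cohorts (sets missing one of a
tree's genes are skipped for that tree with a warning; ties break by
holdout accuracy, then tree ID).

Consensus classification averages per-tree *leaf probabilities* (not hard
votes) and calls a sample hypoxic iff the mean strictly exceeds the
threshold (default 0.5, so a mean of exactly 0.5 is normoxic). The mean
is always bounded by the per-tree extremes, and the number of hypoxic
calls is non-increasing in the threshold.

Since induction is deterministic given a split, a homogeneous cohort can
yield near-identical trees across resamples, concentrating the ensemble
on one or two dominant genes. `generate_tree_population` therefore
optionally assigns each candidate tree a random subspace of the candidate
genes (`features_per_tree`), the classical random-subspace device; the
end-to-end emulation uses 15 of 25. This is what keeps the
missing-gene remedy meaningful: when a dataset lacks a signature gene
(the canonical case being a lncRNA absent from mouse annotation),
`filter_by_available_features` retains exactly the trees that never
consult it, and a diverse ensemble still has such trees.

### Evaluation

Hypoxic is the positive class. `evaluate` reports confusion counts,
accuracy, precision, recall and F1 = 2TP/(2TP+FP+FN); with no positive
calls, precision is reported as 0 with an explicit `precision_undefined`
flag (and F1 is 0). `roc_auc` computes ROC points at every distinct score
plus the (0,0) endpoint and the trapezoid AUC; tied scores collapse to
one point so the AUC equals the Mann–Whitney concordant-pair fraction
(ties counting ½), which the tests verify by explicit pair counting and
against an external reference implementation.

### Spatial sections

Each spot is one sample: ranked over all genes of the matrix, then routed
through the ensemble. All-zero spots are flagged, their (uninformative)
probability reported, and their label set to `"NA"`. 10x-style Matrix
Market triplet directories (plain or gzipped) are the supported exchange
format; gene symbols are deduplicated by suffixing.

## The synthetic-data generator

`generate_cohort` emulates a two-condition bulk RNA-seq corpus:

- per-gene baseline log2 abundances ~ Normal(5, 2.5), giving a
  well-resolved ranking with a low-count tail;
- a configurable number of responsive genes drawn from the mid-expressed
  band (baseline percentile 30–70) — usable signature genes must be
  widely expressed, and a gene at the top of the ranking has no headroom;
- under hypoxia each responsive gene's percentile target rises by the
  configured `effect` (percentile points), jittered per gene by ±25% so
  no single gene is always the best marker; the target percentile is
  converted back to a log-abundance offset by interpolation against the
  baseline distribution (targets above 100 extrapolate past the top gene,
  so `effect=100` puts responsive genes above the whole transcriptome);
- per-gene/per-sample Gaussian noise on log2 abundance (`noise_sd`,
  default 0.5), a per-sample library-size factor (default uniform on
  [0.5, 2]), rounding to integer counts, and Bernoulli dropout (default
  5%) applied before ranking so the tie-at-zero regime of real RNA-seq is
  exercised.

Defaults (1000 genes, 212 samples per class, 25 responsive genes,
20-point effect) approximate the scale and difficulty of the 425-sample
training corpus the method was developed for. Randomness is split into a
*structure* stream (baselines, responsive-gene identities, per-gene
effects) seeded by `structure_seed` and a *sampling* stream seeded by
`seed`; fixing the former while varying the latter draws independent
cohorts from the same gene universe, which is how matched
train/validation/test cohorts and spatial sections are produced. With
`noise_sd=0` and `dropout_p=0` every responsive gene separates the
classes by a single percentile threshold.

`generate_spatial` places spots on a lattice and labels those within a
disc hypoxic — a caricature of a poorly vascularized tumor core. It makes
no attempt at spatial autocorrelation beyond the disc, cell-type mixtures
or time courses, so passing spatial tests demonstrates per-spot
classification mechanics, not robustness to those real-data features.
More generally the generator's samples are i.i.d. within condition: real
cohorts mix cell types, batches and platforms, and results on synthetic
data bound what the pipeline can do, not what it will do on such corpora.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale:
the end-to-end emulation uses 1000 genes / 25 responsive (effect 20) with
60 training samples per class, a 178-gene candidate list (truth plus
random decoys, standing in for a meta-analysis prefilter), 100 MDA
iterations of 200-tree forests, 500 candidate trees, and independent
validation (30/class) and test (40/class) cohorts; the spatial check uses
a 600-gene universe, a 12×12 grid and a 24-spot core at effect 35. These
sizes are the package's own choice of a desk-scale emulation; the
generator's defaults describe the full-scale corpus.

## Known limitations

- The absolute MDA scale is corpus-dependent (redundancy dilutes it), so
  thresholds on raw MDA should be set per corpus, or replaced by rank
  selection.
- Class balance is not enforced in forest subsampling or tree splits;
  heavily unbalanced cohorts will bias accuracy-based selection.
- Gene-ID matching is exact and case-sensitive by default; cross-species
  application relies on the caller mapping orthologs (or dropping
  incompatible trees).
- Percentiles from matrices processed with non-monotone gene-wise
  normalization differ from raw-count percentiles; thresholds are only
  portable between representations related by monotone transforms.
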