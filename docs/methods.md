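# Methods

## Scope and data model

`atlascompare` compares two (or more) single-nucleus RNA-seq atlases that
may come from different species, anatomical regions, or chemistry. The
core container is a `CountAtlas`: a sparse genes × cells raw count matrix,
a gene table (id, symbol, mitochondrial flag), a cell table (donor, sex,
dataset, optional prior label), and derived `normalized` / `scaled`
layers. Genes index rows everywhere; files are exchanged as MatrixMarket
triplet directories (matrix.mtx + features.tsv + barcodes.tsv +
metadata.tsv), read and written through `scipy.io`.

## Quality control

Three filters, applied in a fixed order:

1. genes detected (count > 0) in fewer than `min_cells_per_gene` (default
   3) cells are removed;
2. creation-stage cell filter: cells with at most `min_features_create`
   (default 200) detected genes are removed;
3. subset-stage cell filter: cells with at most `min_features_subset`
   (default 500) detected genes, or at least `max_mito_pct` (default 5%)
   mitochondrial reads, are removed.

Mitochondrial genes are recognized by symbol prefix (`MT-` human, `mt-`
mouse); the prefix list is configurable because the underlying gene set is
annotation-dependent. An empty post-filter atlas is a reported outcome,
not an error. The three-pass order is not mathematically idempotent
(removing cells can, in principle, push a gene back under the min-cells
rule); on realistic inputs the filters converge after one pass and the
test suite checks idempotence on such fixtures.

Normalization is fixed as library-size scaling to 10,000 counts followed
by ln(1+x) — the convention the atlas literature's defaults imply; the
zero pattern is preserved exactly. Scaling is a per-gene z-score using the
n−1 standard deviation, clipped above at +10 with no lower clip,
zero-variance genes mapping to 0.

## Variable features (vst)

Per gene, the log10 variance is regressed on the log10 mean with a local
regression (span 0.3) over all expressed genes; each gene's counts are
standardized by its observed mean and the curve-predicted standard
deviation, clipped at √n_cells, and genes are ranked by the variance of
the clipped standardized values. Ties break by gene id so the ranking is
a deterministic total order. The local regression uses `statsmodels`
`lowess` (locally linear); on inputs too small for a 0.3-span window the
fit falls back to a single global log-log linear fit. This differs from a
degree-2 loess in curvature-heavy regions but ranks planted
high-dispersion genes equivalently in our tests.

## Ortholog harmonization

Mapping classes per source gene, computed from a user-supplied two-column
table restricted to the supplied universes: `unmapped` (no pair),
`one_to_many` (several targets), `many_to_one` (the target is claimed by
several sources — all such sources are excluded as ambiguous), else
`one_to_one`. Only one-to-one genes are renamed and retained; counts are
untouched. Whether target-side genes whose partner was excluded should be
dropped earlier is unspecified in the conventions this package follows;
they are dropped at shared-gene-intersection time and the exclusion report
records per-class counts.

## Anchor integration

Given two atlases scaled over a shared anchor-feature set (the
intersection of each dataset's top-N vst ranking, ordered by rank sum):

- **Canonical space.** K = AᵀB over the scaled feature matrices; a
  truncated SVD (`sklearn.utils.extmath.randomized_svd`, fixed
  random_state) gives `dims` canonical vectors; cell loadings (U and V
  rows) are L2-normalized.
- **Anchors.** Mutual nearest neighbors between datasets (k = `k_anchor`,
  default 5, Euclidean in the normalized canonical space). Candidates are
  kept only if the reference cell lies within the `k_filter` (default 200)
  nearest reference cells of the query in the original scaled feature
  space. Surviving anchors are scored by the overlap of the two cells'
  neighbor sets (k = `k_score` = 30 per dataset in the joint canonical
  space), min–max rescaled between the 1st and 90th percentiles and
  clipped to [0, 1].
- **Correction.** Each query cell receives the score- and distance-
  weighted average (Gaussian kernel on canonical-space distance to the
  query-side anchor cells; bandwidth = distance to the k-th nearest of
  `k_weight` = 100 anchors) of anchor difference vectors (reference −
  query normalized expression), extended to any requested gene set. Zero
  total weight falls back to uniform weights, never an error. The
  reference dataset passes through unchanged, so pipelines can compose:
  a corrected output atlas is a valid input for the next integration.
- **Clustering.** PCA (centering only — corrected values are already on a
  comparable scale) to `n_pcs`; k-nearest-neighbor graph (k = 20 incl.
  self); shared-neighbor Jaccard edge weights with edges under 1/15
  pruned (the ecosystem's default sparsification; without it the graph
  densifies and resolution behaviour shifts); Leiden modularity
  (RBConfiguration) at the configured resolution with a fixed seed, two
  iterations. Labels are renumbered by descending cluster size, ties by
  smallest original community id.

Two presets ship: `within_dataset` (2,000 anchor features, dims 1:10,
15 PCs, resolution 1) and `cross_species` (7,500 anchor features per
dataset, dims 1:10, 30 PCs, resolution 2).

## Marker detection

Cluster-vs-rest: candidates must be detected in ≥ 25% of in-cluster cells
and carry |log2FC| ≥ 0.25, where log2FC compares expm1-back-transformed
normalized means with a +1 pseudocount; candidates get a two-sided
Wilcoxon rank-sum p (normal approximation with tie correction) and
Benjamini–Hochberg adjustment within the cluster's candidate set.
Clusters under 3 cells are skipped with a warning. A merge helper joins
cluster pairs with no significant pairwise markers at these thresholds; it
makes no claim to reproduce manual curation.

## Orthologous-type naming and prevalence

A joint cluster is named after a reference prior label iff strictly more
than half of the cluster's reference cells carry it (a 5/10 tally is a
placeholder). Prevalence bias is computed once after downsampling the
larger dataset uniformly without replacement to the smaller's size:
per type, `prop_a` = 100·n_a/(n_a+n_b); deviation = prop_a − 50 in
percentage points; fold = max(prop)/min(prop), infinite (and counted as
≥ 3-fold) when a type is absent from one side. Summaries: the standard
deviation of signed deviations (n−1 denominator — the natural reading of
"stdev of change from equal proportion"; the |deviation| variant is also
emitted) and the fraction of types at ≥ 3-fold in either direction (the
one-directional count is also emitted). Deviations are antisymmetric
under swapping dataset roles, which the suite tests.

The donor-composition test normalizes for each donor's total cells:
per donor, the percentage of its cells in the cluster; per cluster, a
two-sided Wilcoxon rank-sum between female and male donor vectors, exact
null when both sexes have ≤ 10 donors (and no ties), normal approximation
with continuity correction otherwise. Raw p is primary; a BH column is
provided.

## Signature scores

All genes are placed into `n_bins` = 24 equal-size bins by average
normalized expression; for each signature gene, `n_ctrl` = 25 controls are
drawn uniformly without replacement from its bin, excluding signature
genes (avoiding self-cancellation); the per-cell score is the mean
normalized expression of the signature genes minus the mean over the
pooled controls. The reading "25 controls per signature gene" is the
default; `ctrl_total=True` draws a single bin-matched pool of 25 for the
alternative reading. Scores are seed-reproducible; adding a constant to
every gene cancels exactly. Group comparison uses the Wilcoxon rank-sum;
the per-gene follow-up reuses the marker machinery with no detection or
fold-change filter and BH over the supplied list.

## Surface-gene conservation

The panel is the union over datasets of (top-200 vst genes ∩ supplied
surface-protein list). Pseudobulk is defined on raw counts: per type,
summed counts over its cells divided by the number of cells, so a type's
row is linear in its cells' counts. Conservation per shared type is the
Spearman ρ (average ranks on ties) between panel-restricted pseudobulk
rows of the two datasets; a constant row leaves ρ undefined (reported
missing and dropped from summaries). Distributions of ρ between two
dataset pairs are compared with an unpaired two-tailed t-test; Welch
(unequal variances) is primary since equal variances were never asserted,
and the Student p is emitted alongside.

## Spatial gating

A cell joins a population iff it has at least `min_count` = 3 transcripts
of the gate gene (RBFOX3, excluding non-neuronal cells) and of every
applicable marker ("at least 3" and "more than two" being the same
integer threshold). Markers listed as male-only (e.g. the Y-linked USP9Y)
are skipped in female samples. Gating is conjunctive over markers; a
disjunctive mode exists behind a flag but is off by default. Raising
`min_count` can only shrink a selection (tested). Export is one CSV row
per (cell, population); cells may satisfy several gates.

## Synthetic data generator

The generator states a world in which every stage is verifiable:

- counts are gamma–Poisson (negative binomial) with a single shared
  dispersion θ (default 2, strong overdispersion typical of snRNA-seq);
  the Poisson limit (θ → ∞) is exact in the gamma–Poisson construction;
- per-cell expected library sizes are lognormal (default median 5,000
  counts, log-sd 0.35); each type's relative expression vector is a
  normalized exponential of per-gene log-means: a N(0,1) baseline plus
  ln(2)·marker_log2fc for that type's markers (default 2 log2-fold, 10
  markers per type), a mitochondrial boost (default 0), and per-dataset
  N(0, surface_divergence_sd) jitter on surface genes — the planted
  conservation divergence;
- 2% of genes are mitochondrial (`MT-` prefix) at baseline expression:
  nuclear preparations carry little mitochondrial RNA, and the default
  world must itself pass the 5% QC rule it feeds;
- cells are partitioned round-robin into ≥ 4 donors alternating F/M;
  donor effects are optional library-size scalings only, keeping the
  ground truth for the sex-composition test clean; sex-specific types are
  planted by zeroing a type's probability in male donors;
- the ortholog table renames genes `g → H-g` with exact round(fraction·n)
  quotas of unmapped and one-to-many (two-target) genes;
- spatial cells draw Poisson(λ_high = 8) transcripts for their
  population's markers and the gate gene and Poisson(λ_low = 0.2)
  elsewhere, with uniform coordinates.

What the generator does **not** emulate: ambient RNA, doublets,
batch-specific dropout curves, gene–gene correlation beyond type
structure, donor-specific expression effects, or spatial segmentation
error. A green test therefore establishes that the statistics and
algorithms recover what was planted under clean NB sampling — not that
they are robust to artefacts absent from this world. The headline
full-scale comparative numbers of the motivating studies depend on the
deposited datasets and manual curation and are not reproduced here; the
suite verifies the estimators on planted truths instead (e.g. a planted
3.5-fold type is flagged with no false flags in ≥ 9/10 seeds at 10,000
cells per side).

## Numerical choices

- Randomized SVD and PCA use fixed seeds; Leiden takes an explicit seed;
  subsampling, control-gene draws and the generator all derive from
  integer seeds, so every report is bit-reproducible under a fixed
  configuration (the pipeline writes a provenance manifest with the
  config hash).
- Wilcoxon tests switch from the exact null to the normal approximation
  at group size > 10 (donors) / > 20 (cells) or in the presence of ties.
- Equal-depth sampling happens once before the prevalence computation,
  not per type.
- The `k_filter` gene-space check is skipped when the reference has fewer
  cells than `k_filter`.
- Fold ratios with an empty side are reported as infinite rather than
  capped.

## Limitations

- The anchor algorithm fixes internals (SVD-CCA, MNN, quantile-rescaled
  shared-neighbor scores) that published tools leave partially
  unspecified; parameter defaults follow their published descriptions,
  but exact numeric agreement with any specific release is not a goal.
- The lowess trend (locally linear) stands in for a degree-2 loess.
- Cluster merging and doublet cleanup are declarative approximations of
  manual curation steps.
- At very small gene counts the vst trend degenerates to a global fit;
  rankings remain deterministic but less informative.
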