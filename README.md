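# atlascompare

Comparative analysis of single-nucleus RNA-seq cell-type atlases across
species, anatomical regions, and datasets — plus the spatial-transcriptomics
follow-up that places the resulting neuron types in tissue.

`atlascompare` packages the computational conventions used to compare
spinal-cord neuron atlases between mouse and human (and between human
cervical and lumbar segments) as a tested, reusable pipeline:

1. **QC and layers** — genes kept when detected in ≥ 3 cells; cells kept
   with > 200 detected genes at object creation, then > 500 detected genes
   and < 5% mitochondrial reads; library-size normalization to 10⁴ followed
   by ln(1+x); per-gene z-scaling clipped at +10.
2. **Ortholog harmonization** — a two-column ortholog table maps the source
   species into the target namespace; genes with no ortholog, with several
   orthologs (one-to-many), or sharing a target (ambiguous, many-to-one)
   are excluded; paired atlases are restricted to their shared gene space.
3. **Anchor integration** — variance-stabilized (vst) feature ranking per
   dataset; the anchor feature set is the intersection of each dataset's
   top-N ranking; a canonical correlation basis comes from the SVD of the
   cross-product of the scaled feature matrices K = AᵀB; anchors are mutual
   nearest neighbors in the L2-normalized canonical space, filtered in gene
   space and scored by shared-neighbor overlap; anchor difference vectors
   correct the query expression; the corrected matrix is clustered with
   Leiden on a shared-nearest-neighbor Jaccard graph (30 PCs, resolution 2
   for cross-species work; 15 PCs, resolution 1 within a dataset).
4. **Orthologous type naming** — a joint cluster inherits a reference type
   name iff strictly more than half of its reference cells carry that
   prior label; otherwise it keeps a placeholder.
5. **Prevalence bias** — after downsampling both datasets to equal depth,
   each type's cells are pooled and the percentage from dataset A is
   computed; the deviation from 50% is the prevalence bias. Summaries:
   the standard deviation of the signed deviations across types and the
   fraction of types with a ≥ 3-fold proportion ratio.
6. **Donor sex composition** — per-donor cluster proportions (normalizing
   for each donor's total cells) compared between sexes with a two-sided
   Wilcoxon rank-sum test (exact null for ≤ 10 donors per sex).
7. **Signature scores** — a gene set's score per cell is its mean
   normalized expression minus that of expression-matched control genes
   drawn from the same average-expression bins (24 bins, 25 controls per
   signature gene), as used for ALS-related gene panels in motor neurons;
   group comparison by Wilcoxon, per-gene follow-up with BH correction.
8. **Surface-gene conservation** — the union over datasets of the top-200
   most variable genes intersected with a cell-surface protein list forms
   a panel; per-type pseudobulk profiles (summed counts / cells) are
   compared across datasets by Spearman ρ per type, and ρ distributions
   are compared between dataset pairs with an unpaired t-test (Welch).
9. **Spatial gating** — a spatial cell joins a neuronal population when it
   carries ≥ 3 transcripts of the neuronal gate gene (RBFOX3) and of every
   applicable population marker; Y-linked markers are skipped in female
   samples.

A synthetic atlas generator (`atlascompare.simgen`) produces
negative-binomial count matrices with planted type markers, donor/sex
structure, proportion shifts, surface-gene divergence and an ortholog
table with one-to-one / one-to-many / unmapped entries, so the entire
pipeline runs and is verified without any external download.

## Worked example

Simulate two datasets sharing six neuron types, with type `T00` planted at
30% prevalence in dataset A but 10% in dataset B (a three-fold shift),
integrate them, name the joint clusters, and compute the prevalence-bias
report:

```python
import numpy as np
from atlascompare import (SimConfig, simulate_atlas, filter_qc, lognormalize,
                          scale_features, anchor_features, find_anchors,
                          integrate_expression, cluster_graph,
                          transfer_majority_labels, equal_depth_subsample,
                          prevalence_bias)
from atlascompare.qc import QcThresholds

cfg = SimConfig(
    cells_per_dataset=(1500, 1200), n_genes=800, n_types=6,
    type_proportions=(
        (0.30, 0.14, 0.14, 0.14, 0.14, 0.14),
        (0.10, 0.18, 0.18, 0.18, 0.18, 0.18),
    ),
    seed=0,
)
atlases, truth = simulate_atlas(cfg)
thr = QcThresholds(min_features_create=100, min_features_subset=200)
a, _ = filter_qc(atlases[0], thr)
b, _ = filter_qc(atlases[1], thr)
a, b = lognormalize(a), lognormalize(b)

features = anchor_features(a, b, 300)
a, b = scale_features(a, features), scale_features(b, features)
anchors = find_anchors(a, b, features, dims=10)
corrected, cells = integrate_expression(anchors, a, b, features)
labels = cluster_graph(corrected, n_pcs=15, k_neighbors=20, resolution=1.0, seed=0)

ref_mask = np.arange(len(cells)) < a.n_cells
label_map = transfer_majority_labels(
    labels, ref_mask, np.r_[a.cells["prior_label"], b.cells["prior_label"]])
named = label_map.loc[labels, "name"].to_numpy()
ia, ib = np.flatnonzero(ref_mask), np.flatnonzero(~ref_mask)
sa, sb = equal_depth_subsample(ia, ib, seed=0)
keep = np.r_[sa, sb]
report = prevalence_bias(named[keep], ref_mask[keep])
print(report.table.round(2))
print(f"stdev of deviation = {report.stdev_deviation:.2f} % points; "
      f"{100 * report.frac_threefold:.0f}% of types three-fold enriched")
```

Output:

```
      n_a  n_b  prop_a  deviation  fold
type
T00   371  129   74.20      24.20  2.88
T01   183  208   46.80      -3.20  1.14
T02   178  228   43.84      -6.16  1.28
T03   154  210   42.31      -7.69  1.36
T04   145  207   41.19      -8.81  1.43
T05   169  218   43.67      -6.33  1.29
stdev of deviation = 12.65 % points; 0% of types three-fold enriched
```

All six joint clusters were named by majority vote from the reference
dataset's prior labels. The planted shift on `T00` is recovered: after
equal-depth sampling, 74% of pooled `T00` cells come from dataset A
(+24 percentage points from parity, a 2.9-fold ratio — the estimate of the
planted 3-fold shift; its shortfall reflects binomial sampling noise at
~500 pooled cells). The remaining types sit near parity, and the spread of
signed deviations (12.65 points) is dominated by the one planted shift.

## Command line

Every stage is also a subcommand of the `atlascompare` entry point:
`simulate`, `qc`, `orthology`, `integrate`, `compare`, `score`, `conserve`,
`gate`, `run` (full pipeline) and `fixtures` (packaged test datasets).
For example:

```bash
atlascompare run --seed 0 --out runs/demo
atlascompare gate --table cells.csv --gates gates.yaml --sex F --out gated/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic fixtures at the packaged "small" scale
(2 × 3,000 cells, 2,000 genes, 12 types), runs every pipeline stage —
simulation, QC, ortholog harmonization, anchor integration, Leiden
clustering, majority naming, equal-depth prevalence statistics, donor
composition, signature scoring, surface-gene conservation, spatial gating —
from scratch under the given seed, and writes the result file. See
`docs/methods.md` for the modelling choices and the limits of what the
synthetic world establishes.
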