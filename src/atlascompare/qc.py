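"""Quality control and expression-layer derivation.

Filtering conventions: genes detected in fewer than 3 cells are dropped;
cells are dropped at object creation when they carry at most 200 detected
genes, and at the subset stage when they carry at most 500 detected genes
or at least 5% mitochondrial reads.  Normalization is library-size scaling
to 10,000 counts followed by ln(1+x); scaling is per-gene z-scoring
(n-1 denominator) clipped above at 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas import CountAtlas


@dataclass
class QcThresholds:
    min_cells_per_gene: int = 3
    min_features_create: int = 200
    min_features_subset: int = 500
    max_mito_pct: float = 5.0

    def validate(self) -> None:
        for name in ("min_cells_per_gene", "min_features_create",
                     "min_features_subset", "max_mito_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")


def filter_qc(
    atlas: CountAtlas, thresholds: QcThresholds | None = None
) -> tuple[CountAtlas, pd.Series]:
    """Apply the three QC filters in order; return the atlas and a report.

    Order: (1) genes detected (count > 0) in fewer than
    ``min_cells_per_gene`` cells removed; (2) creation-stage cell filter,
    cells with <= ``min_features_create`` detected genes removed; (3)
    subset-stage cell filter, cells with <= ``min_features_subset``
    detected genes or mito percentage >= ``max_mito_pct`` removed.  An
    empty result is returned (with a warning flag in the report), not an
    error.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()

    detected = (atlas.counts > 0)
    cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= thresholds.min_cells_per_gene
    out = atlas.subset(gene_mask=gene_keep)
    n_genes_removed = int((~gene_keep).sum())

    feats = out.detected_genes_per_cell()
    create_keep = feats > thresholds.min_features_create
    n_create_removed = int((~create_keep).sum())
    out = out.subset(cell_mask=create_keep)

    feats = out.detected_genes_per_cell()
    mito_pct = 100.0 * out.mito_fraction()
    subset_keep = (feats > thresholds.min_features_subset) & (
        mito_pct < thresholds.max_mito_pct
    )
    n_feat_removed = int((feats <= thresholds.min_features_subset).sum())
    n_mito_removed = int(
        ((mito_pct >= thresholds.max_mito_pct) & (feats > thresholds.min_features_subset)).sum()
    )
    out = out.subset(cell_mask=subset_keep)

    report = pd.Series(
        {
            "genes_removed_min_cells": n_genes_removed,
            "cells_removed_create": n_create_removed,
            "cells_removed_min_features": n_feat_removed,
            "cells_removed_mito": n_mito_removed,
            "genes_retained": out.n_genes,
            "cells_retained": out.n_cells,
            "empty_result": int(out.n_cells == 0 or out.n_genes == 0),
        }
    )
    return out, report


def lognormalize(atlas: CountAtlas, scale_factor: float = 1e4) -> CountAtlas:
    """Attach the normalized layer: ln(1 + count * scale_factor / libsize).

    Preserves the zero pattern exactly (zeros map to zeros).  Cells with
    zero library size are an error.
    """
    lib = atlas.library_sizes().astype(float)
    if np.any(lib == 0):
        bad = atlas.cell_ids[lib == 0].tolist()
        raise ValueError(f"cells with zero library size: {bad[:5]}")
    mat = sp.csc_matrix(atlas.counts, dtype=float)
    mat = mat.multiply(scale_factor / lib[None, :]).tocsr()
    mat.data = np.log1p(mat.data)
    out = atlas.copy()
    out.layers["normalized"] = sp.csr_matrix(mat)
    return out


def scale_features(
    atlas: CountAtlas, features=None, clip_max: float = 10.0
) -> CountAtlas:
    """Attach the scaled layer: per-gene z-score of the normalized layer.

    Restricted to ``features`` (default: all genes).  Uses the n-1
    standard deviation; zero-variance genes map to 0; values are clipped
    above at ``clip_max`` only (no lower clip).
    """
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer required; run lognormalize first")
    if features is None:
        features = atlas.genes.index.to_numpy()
    features = np.asarray(list(features))
    if len(features) == 0:
        raise ValueError("empty feature list")
    missing = set(features) - set(atlas.genes.index)
    if missing:
        raise ValueError(f"features absent from atlas: {sorted(missing)[:5]}")
    idx = atlas.genes.index.get_indexer(features)
    norm = atlas.layers["normalized"][idx, :]
    dense = np.asarray(norm.todense(), dtype=float)
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=1, keepdims=True) if dense.shape[1] > 1 else np.ones_like(mean)
    scaled = np.where(sd > 0, (dense - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    scaled = np.minimum(scaled, clip_max)
    out = atlas.copy()
    out.layers["scaled"] = scaled
    out.layers_genes["scaled"] = features
    return out


def drop_doublet_clusters(
    atlas: CountAtlas,
    labels: pd.Series,
    rules: list[dict],
    min_mean_norm: float = 0.5,
) -> tuple[CountAtlas, list]:
    """Declarative doublet cleanup: drop clusters co-expressing two marker sets.

    Each rule is ``{"set_a": [...], "set_b": [...]}``; a cluster is dropped
    when the mean normalized expression of both sets exceeds
    ``min_mean_norm``.  Mirrors a manual marker-based cleanup as a
    testable rule file rather than an algorithmic doublet detector.
    """
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer required")
    norm = atlas.layers["normalized"]
    dropped = []
    for cl in pd.unique(labels):
        mask = (labels == cl).to_numpy()
        for rule in rules:
            means = []
            for key in ("set_a", "set_b"):
                genes = [g for g in rule[key] if g in atlas.genes.index]
                if not genes:
                    means.append(0.0)
                    continue
                gi = atlas.genes.index.get_indexer(genes)
                means.append(float(norm[gi, :][:, mask].mean()))
            if means[0] > min_mean_norm and means[1] > min_mean_norm:
                dropped.append(cl)
                break
    keep = ~labels.isin(dropped).to_numpy()
    return atlas.subset(cell_mask=keep), dropped
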