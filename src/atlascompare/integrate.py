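"""Anchor-based cross-dataset integration, graph clustering and markers.

The anchoring procedure: a canonical correlation basis is obtained from
the singular value decomposition of the cross-product of the two scaled
feature matrices; cells projected onto the canonical vectors are
L2-normalized; anchors are mutual nearest neighbors between datasets in
this space, filtered by a nearest-neighbor check in the original feature
space and scored by shared-neighbor overlap.  Anchor difference vectors
then correct the query dataset's expression toward the reference, the
corrected matrix is reduced by PCA, and a shared-nearest-neighbor Jaccard
graph is clustered with Leiden modularity optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd
from statsmodels.stats.multitest import multipletests

from .atlas import CountAtlas

SNN_PRUNE = 1.0 / 15.0  # drop SNN edges with Jaccard weight below this


@dataclass
class AnchorSet:
    """Matched cell pairs across two datasets with scores in [0, 1]."""

    anchors: pd.DataFrame  # columns cell_a, cell_b (positional indices), score
    features: list
    dims: int
    emb_a: np.ndarray = field(repr=False, default=None)
    emb_b: np.ndarray = field(repr=False, default=None)


def _scaled_matrix(atlas: CountAtlas, features) -> np.ndarray:
    """Scaled layer rows for ``features`` (features x cells)."""
    if "scaled" not in atlas.layers:
        raise ValueError("atlas lacks a scaled layer; run scale_features first")
    layer_genes = pd.Index(atlas.layers_genes.get("scaled", atlas.genes.index))
    idx = layer_genes.get_indexer(features)
    if (idx < 0).any():
        missing = [f for f, i in zip(features, idx) if i < 0]
        raise ValueError(f"features missing from scaled layer: {missing[:5]}")
    return np.asarray(atlas.layers["scaled"])[idx, :]


def _l2_normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.where(norms > 0, norms, 1.0)


def _knn_indices(query: np.ndarray, ref: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k, ref.shape[0])).fit(ref)
    return nn.kneighbors(query, return_distance=False)


def find_anchors(
    a: CountAtlas,
    b: CountAtlas,
    features,
    dims: int = 10,
    k_anchor: int = 5,
    k_filter: int = 200,
    k_score: int = 30,
) -> AnchorSet:
    """Find cross-dataset anchor pairs by CCA + mutual nearest neighbors.

    ``dims`` canonical vectors are taken from the SVD of the cross-product
    of the scaled feature matrices.  Mutual nearest neighbors (k =
    ``k_anchor``) in the row-normalized canonical space become candidate
    anchors; each is kept only if its reference cell lies within the
    ``k_filter`` nearest reference cells of the query in the original
    feature space, then scored by shared-neighbor overlap among
    ``k_score`` neighbors, min-max rescaled between the 1st and 90th
    percentiles and clipped to [0, 1].
    """
    features = list(features)
    if dims > len(features):
        raise ValueError("dims cannot exceed the number of features")
    A = _scaled_matrix(a, features)
    B = _scaled_matrix(b, features)
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < dims or n_b < dims:
        raise ValueError("fewer cells than canonical dimensions")

    K = A.T @ B  # n_a x n_b cross-product of scaled matrices
    U, s, Vt = randomized_svd(K, n_components=dims, random_state=0)
    emb_a = _l2_normalize_rows(U[:, :dims])
    emb_b = _l2_normalize_rows(Vt.T[:, :dims])

    # mutual nearest neighbors across datasets in canonical space
    nn_ab = _knn_indices(emb_a, emb_b, k_anchor)  # for each a-cell: b neighbors
    nn_ba = _knn_indices(emb_b, emb_a, k_anchor)
    ba_sets = [set(row) for row in nn_ba]
    pairs = [
        (i, j)
        for i in range(n_a)
        for j in nn_ab[i]
        if i in ba_sets[j]
    ]

    # feature-space filter: reference cell within k_filter NNs of the query
    if pairs and k_filter < n_a:
        nn_filter = _knn_indices(B.T, A.T, k_filter)
        filt_sets = [set(row) for row in nn_filter]
        pairs = [(i, j) for i, j in pairs if i in filt_sets[j]]

    if not pairs:
        return AnchorSet(
            anchors=pd.DataFrame(columns=["cell_a", "cell_b", "score"]),
            features=features, dims=dims, emb_a=emb_a, emb_b=emb_b,
        )

    # shared-neighbor scoring in the joint canonical space
    all_emb = np.vstack([emb_a, emb_b])
    nbr_in_a = _knn_indices(all_emb, emb_a, k_score)
    nbr_in_b = _knn_indices(all_emb, emb_b, k_score) + n_a
    nbr_sets = [
        set(nbr_in_a[i]) | set(nbr_in_b[i]) for i in range(n_a + n_b)
    ]
    raw = np.array(
        [len(nbr_sets[i] & nbr_sets[n_a + j]) for i, j in pairs], dtype=float
    )
    lo, hi = np.quantile(raw, 0.01), np.quantile(raw, 0.90)
    if hi > lo:
        score = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    else:
        score = np.ones_like(raw)

    anchors = pd.DataFrame(
        {"cell_a": [p[0] for p in pairs],
         "cell_b": [p[1] for p in pairs],
         "score": score}
    )
    return AnchorSet(anchors=anchors, features=features, dims=dims,
                     emb_a=emb_a, emb_b=emb_b)


def mutual_nearest_neighbors_bruteforce(
    emb_a: np.ndarray, emb_b: np.ndarray, k: int
) -> set:
    """Exhaustive O(n^2) MNN pairs — the independent oracle for tests."""
    d = np.linalg.norm(emb_a[:, None, :] - emb_b[None, :, :], axis=2)
    pairs = set()
    for i in range(d.shape[0]):
        nb = np.argsort(d[i])[:k]
        for j in nb:
            na = np.argsort(d[:, j])[:k]
            if i in na:
                pairs.add((i, int(j)))
    return pairs


def integrate_expression(
    anchor_set: AnchorSet,
    a: CountAtlas,
    b: CountAtlas,
    genes,
    k_weight: int = 100,
) -> tuple[np.ndarray, pd.Index]:
    """Correct the query (``b``) toward the reference using anchor vectors.

    Each query cell receives a correction equal to the score- and
    distance-weighted average (Gaussian kernel over canonical-embedding
    distance; bandwidth = distance to the k-th nearest anchor) of the
    anchor difference vectors (reference minus query normalized
    expression) over ``genes``.  The reference is returned unchanged.
    Returns (corrected genes x all-cells matrix on the normalized scale,
    combined cell index a-then-b).
    """
    anchors = anchor_set.anchors
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    genes = list(genes)
    ia = a.genes.index.get_indexer(genes)
    ib = b.genes.index.get_indexer(genes)
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("genes missing from one of the atlases")
    ref = np.asarray(a.layers["normalized"][ia, :].todense())
    qry = np.asarray(b.layers["normalized"][ib, :].todense())

    ai = anchors["cell_a"].to_numpy()
    bi = anchors["cell_b"].to_numpy()
    scores = anchors["score"].to_numpy(dtype=float)
    diffs = ref[:, ai] - qry[:, bi]  # genes x n_anchors

    anchor_emb = anchor_set.emb_b[bi]  # query-side anchor positions
    k = min(k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=k).fit(anchor_emb)
    dist, idx = nn.kneighbors(anchor_set.emb_b)

    corrected_q = qry.copy()
    for c in range(qry.shape[1]):
        d = dist[c]
        nearest = idx[c]
        bw = d[-1]
        if bw > 0:
            w = scores[nearest] * np.exp(-((d / bw) ** 2))
        else:
            w = scores[nearest].copy()
        if w.sum() <= 0:
            w = np.ones(k)
        w = w / w.sum()
        corrected_q[:, c] += diffs[:, nearest] @ w

    corrected = np.hstack([ref, corrected_q])
    cell_index = a.cells.index.append(b.cells.index)
    return corrected, cell_index


def cluster_graph(
    corrected: np.ndarray,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    resolution: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden clustering of an SNN graph built on PCA of the corrected matrix.

    PCA centers (but does not re-scale) the genes x cells input; a
    k-nearest-neighbor graph over the top ``n_pcs`` components is
    converted to shared-nearest-neighbor Jaccard weights (edges below
    1/15 pruned); Leiden modularity optimization runs at the given
    ``resolution`` with a fixed seed.  Labels 0..K-1 are ordered by
    descending cluster size (ties by smallest original community id).
    """
    X = np.asarray(corrected).T  # cells x genes
    n_cells = X.shape[0]
    if k_neighbors >= n_cells:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full" if min(X.shape) < 500 else "randomized",
              random_state=seed).fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pcs)
    knn = nn.kneighbors_graph(pcs, mode="connectivity")  # includes self? no: k nearest excl self
    # include self so shared-neighbor counts match the usual convention
    knn = knn + sp.identity(n_cells, format="csr")
    shared = knn @ knn.T
    shared = sp.coo_matrix(shared)
    k_tot = k_neighbors + 1
    jac = shared.data / (2 * k_tot - shared.data)
    mask = (jac >= SNN_PRUNE) & (shared.row != shared.col)
    edges = np.stack([shared.row[mask], shared.col[mask]], axis=1)
    weights = jac[mask]
    upper = edges[:, 0] < edges[:, 1]
    edges, weights = edges[upper], weights[upper]

    g = ig.Graph(n=n_cells, edges=[tuple(e) for e in edges])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(weights),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.array(part.membership)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


def find_markers(
    atlas: CountAtlas,
    labels,
    min_frac: float = 0.25,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster marker detection (cluster vs rest).

    Candidate genes must be detected (count > 0) in at least ``min_frac``
    of in-cluster cells and show |log2FC| >= ``min_log2fc``, where log2FC
    compares expm1-back-transformed normalized means with a +1
    pseudocount.  Candidates get a two-sided Wilcoxon rank-sum p on
    normalized values, Benjamini-Hochberg adjusted within the cluster's
    candidate set.  Clusters of size < 3 are skipped with a warning.
    """
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer required")
    labels = pd.Series(np.asarray(labels), index=atlas.cells.index)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    norm = np.asarray(atlas.layers["normalized"].todense())
    detected = np.asarray((atlas.counts > 0).todense())
    expr = np.expm1(norm)

    rows = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped")
            continue
        frac_in = detected[:, mask].mean(axis=1)
        frac_out = detected[:, ~mask].mean(axis=1)
        mean_in = expr[:, mask].mean(axis=1)
        mean_out = expr[:, ~mask].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        cand = (frac_in >= min_frac) & (np.abs(log2fc) >= min_log2fc)
        if not cand.any():
            continue
        x_in = norm[cand][:, mask]
        x_out = norm[cand][:, ~mask]
        res = stats.mannwhitneyu(
            x_in, x_out, axis=1, alternative="two-sided", method="asymptotic"
        )
        pvals = np.atleast_1d(res.pvalue)
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        gi = np.flatnonzero(cand)
        for pos, g in enumerate(gi):
            rows.append(
                {
                    "cluster": cl,
                    "gene": atlas.genes.index[g],
                    "log2fc": log2fc[g],
                    "pct_in": frac_in[g],
                    "pct_out": frac_out[g],
                    "p": pvals[pos],
                    "p_adj": p_adj[pos],
                }
            )
    table = pd.DataFrame(
        rows, columns=["cluster", "gene", "log2fc", "pct_in", "pct_out", "p", "p_adj"]
    )
    if len(table):
        table = table.sort_values(
            ["cluster", "log2fc"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
        table["significant"] = table["p_adj"] < alpha
    else:
        table["significant"] = pd.Series(dtype=bool)
    return table


def merge_indistinct_clusters(
    atlas: CountAtlas,
    labels,
    min_frac: float = 0.25,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
) -> np.ndarray:
    """Merge cluster pairs with no significant pairwise markers at the stated thresholds."""
    labels = np.asarray(labels)
    merged = labels.copy()
    changed = True
    while changed:
        changed = False
        uniq = pd.unique(merged)
        for i, c1 in enumerate(uniq):
            for c2 in uniq[i + 1:]:
                mask = np.isin(merged, [c1, c2])
                sub = atlas.subset(cell_mask=mask)
                sub_labels = merged[mask]
                try:
                    table = find_markers(sub, sub_labels, min_frac, min_log2fc, alpha)
                except ValueError:
                    continue
                if len(table) == 0 or not table["significant"].any():
                    merged[merged == c2] = c1
                    changed = True
                    break
            if changed:
                break
    return merged
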