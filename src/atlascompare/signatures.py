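"""Gene-signature scoring with expression-matched binned controls.

A cell's signature score is the mean normalized expression of the gene
set minus the mean over control genes sampled from the same average-
expression bins, so a positive score means the set is expressed above
genes of comparable abundance.  Group comparison uses a Wilcoxon
rank-sum; the per-gene follow-up reuses the marker-test machinery without
detection or fold-change filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import CountAtlas


@dataclass
class SignatureScore:
    scores: pd.Series  # per cell
    gene_set: list
    control_genes: list
    n_bins: int
    n_ctrl: int
    seed: int


def _expression_bins(mean_expr: pd.Series, n_bins: int) -> pd.Series:
    """Assign every gene to one of ``n_bins`` equal-size bins by mean expression."""
    order = mean_expr.sort_values(kind="mergesort").index
    bins = pd.Series(0, index=mean_expr.index, dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    atlas: CountAtlas,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 25,
    seed: int = 0,
    ctrl_total: bool = False,
) -> SignatureScore:
    """Binned-control signature score per cell.

    All genes are binned into ``n_bins`` equal-size bins by average
    normalized expression across cells; for each signature gene,
    ``n_ctrl`` control genes are sampled uniformly without replacement
    from its bin (signature genes excluded from control pools); the score
    is the mean normalized expression of the signature genes minus the
    mean over the pooled controls.  ``ctrl_total=True`` instead samples a
    single pool of ``n_ctrl`` controls matched to the bins of the set.
    Signature genes absent from the atlas are dropped with a warning.
    """
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer required")
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in atlas.genes.index]
    missing = [g for g in gene_set if g not in atlas.genes.index]
    if missing:
        warnings.warn(f"signature genes absent from atlas: {missing}")
    if not present:
        raise ValueError("no signature gene present in the atlas")

    norm = atlas.layers["normalized"]
    mean_expr = pd.Series(
        np.asarray(norm.mean(axis=1)).ravel(), index=atlas.genes.index
    )
    bins = _expression_bins(mean_expr, n_bins)
    rng = np.random.default_rng(seed)
    sig_set = set(present)

    controls: list = []
    if ctrl_total:
        # one pooled draw of n_ctrl controls, bin-matched to the set
        pool_bins = [bins[g] for g in present]
        candidates = bins.index[bins.isin(set(pool_bins)) & ~bins.index.isin(sig_set)]
        take = min(n_ctrl, len(candidates))
        controls = list(rng.choice(np.asarray(candidates), size=take, replace=False))
    else:
        for g in present:
            pool = bins.index[(bins == bins[g]) & ~bins.index.isin(sig_set)]
            take = min(n_ctrl, len(pool))
            if take == 0:
                continue
            controls.extend(rng.choice(np.asarray(pool), size=take, replace=False))
    if not controls:
        raise ValueError("no control genes available; decrease n_bins or n_ctrl")

    gi = atlas.genes.index.get_indexer(present)
    ci = atlas.genes.index.get_indexer(pd.unique(pd.Series(controls)))
    sig_mean = np.asarray(norm[gi, :].mean(axis=0)).ravel()
    # pooled control mean counts multiplicity of repeated control draws
    ctrl_counts = pd.Series(controls).value_counts()
    cw = ctrl_counts.reindex(pd.unique(pd.Series(controls))).to_numpy(dtype=float)
    ctrl_dense = np.asarray(norm[ci, :].todense())
    ctrl_mean = (cw[:, None] * ctrl_dense).sum(axis=0) / cw.sum()
    scores = pd.Series(sig_mean - ctrl_mean, index=atlas.cells.index)
    return SignatureScore(
        scores=scores, gene_set=present, control_genes=list(controls),
        n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
    )


def score_group_test(score: SignatureScore, group_of_cell) -> dict:
    """Two-sided Wilcoxon rank-sum of signature scores between two groups.

    ``group_of_cell`` is boolean (True = group of interest).  Uses the
    normal approximation with tie correction for groups larger than 20,
    the exact null otherwise.
    """
    group = np.asarray(group_of_cell, dtype=bool)
    x = score.scores.to_numpy()[group]
    y = score.scores.to_numpy()[~group]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    use_exact = max(len(x), len(y)) <= 20 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    return {
        "mean_in": float(x.mean()),
        "mean_out": float(y.mean()),
        "W": float(res.statistic),
        "p": float(res.pvalue),
    }


def per_gene_group_de(atlas: CountAtlas, group_of_cell, gene_list) -> pd.DataFrame:
    """Per-gene group comparison over a fixed gene list (no filters).

    Same log2 fold change and Wilcoxon machinery as marker detection but
    restricted to ``gene_list``, with Benjamini-Hochberg adjustment over
    the list.  Genes absent from the atlas get a row with ``missing=True``.
    """
    gene_list = list(dict.fromkeys(gene_list))
    if not gene_list:
        raise ValueError("empty gene list")
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer required")
    group = np.asarray(group_of_cell, dtype=bool)
    present = [g for g in gene_list if g in atlas.genes.index]
    gi = atlas.genes.index.get_indexer(present)
    norm = np.asarray(atlas.layers["normalized"][gi, :].todense())
    expr = np.expm1(norm)
    mean_in = expr[:, group].mean(axis=1)
    mean_out = expr[:, ~group].mean(axis=1)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    res = stats.mannwhitneyu(
        norm[:, group], norm[:, ~group], axis=1,
        alternative="two-sided", method="asymptotic",
    )
    pvals = np.atleast_1d(res.pvalue)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")

    rows = {g: {"gene": g, "log2fc": np.nan, "p": np.nan, "p_adj": np.nan,
                "missing": True} for g in gene_list}
    for k, g in enumerate(present):
        rows[g] = {"gene": g, "log2fc": float(log2fc[k]), "p": float(pvals[k]),
                   "p_adj": float(p_adj[k]), "missing": False}
    return pd.DataFrame([rows[g] for g in gene_list]).set_index("gene")
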