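"""Variance-stabilized highly-variable-gene selection.

Implements the vst ranking: a local regression of log10 variance on log10
mean over all genes predicts each gene's expected standard deviation;
counts are standardized by the observed mean and the predicted sd,
clipped at sqrt(n_cells), and genes are ranked by the variance of the
clipped standardized values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .atlas import CountAtlas

LOESS_SPAN = 0.3


def select_variable_features(atlas: CountAtlas, n: int) -> pd.DataFrame:
    """Rank genes by standardized variance; return the top ``n``.

    Returns a DataFrame indexed by gene id with columns
    ``standardized_variance`` and ``rank`` (1 = most variable).  Ties are
    broken by gene id so the ranking is a deterministic total order.
    Constant genes have standardized variance 0 and rank last.
    """
    if atlas.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n > atlas.n_genes:
        warnings.warn(
            f"requested {n} features but atlas has {atlas.n_genes} genes; returning all"
        )
        n = atlas.n_genes
    ranking = feature_ranking(atlas)
    return ranking.head(n)


def feature_ranking(atlas: CountAtlas) -> pd.DataFrame:
    """Full vst ranking over every gene (most to least variable)."""
    X = atlas.counts.tocsr().astype(float)
    n_cells = atlas.n_cells
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n_cells / (n_cells - 1)
    var = np.maximum(var, 0.0)

    std_var = np.zeros(atlas.n_genes)
    usable = (var > 0) & (mean > 0)
    if usable.sum() >= 2:
        lx = np.log10(mean[usable])
        ly = np.log10(var[usable])
        # widen the window on small inputs so each local fit sees >= 5 points
        frac = LOESS_SPAN if usable.sum() * LOESS_SPAN >= 5 else 1.0
        fitted = lowess(ly, lx, frac=frac, xvals=lx)
        if np.isnan(fitted).any():  # degenerate window: global log-log fit
            coef = np.polyfit(lx, ly, deg=1)
            fitted = np.polyval(coef, lx)
        sd_pred = np.sqrt(10.0**fitted)
        clip = np.sqrt(n_cells)
        dense = np.asarray(X[usable, :].todense())
        z = (dense - mean[usable][:, None]) / sd_pred[:, None]
        z = np.minimum(z, clip)
        std_var[usable] = z.var(axis=1, ddof=1)

    order = pd.DataFrame(
        {"standardized_variance": std_var}, index=atlas.genes.index
    )
    order = order.sort_values(
        by=["standardized_variance"], ascending=False, kind="mergesort"
    )
    # stable sort then tie-break by gene id within equal variances
    order = (
        order.reset_index()
        .sort_values(by=["standardized_variance", "gene_id"],
                     ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
    )
    order["rank"] = np.arange(1, len(order) + 1)
    return order


def anchor_features(a: CountAtlas, b: CountAtlas, n_each: int) -> list[str]:
    """Shared anchor feature set: intersection of each dataset's top-``n_each``.

    Ordered by the sum of the two ranks (most jointly variable first).
    """
    if n_each <= 0:
        raise ValueError("n_each must be positive")
    ra = select_variable_features(a, n_each)
    rb = select_variable_features(b, n_each)
    shared = ra.index.intersection(rb.index)
    if len(shared) == 0:
        raise ValueError(
            "no overlap between variable-feature sets; increase n_each"
        )
    rank_sum = ra.loc[shared, "rank"] + rb.loc[shared, "rank"]
    return rank_sum.sort_values(kind="mergesort").index.tolist()
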