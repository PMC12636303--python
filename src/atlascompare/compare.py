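"""Joint-cluster naming and cell-type composition statistics.

Joint clusters are named after a reference labeling by strict majority
vote (> 1/2 of the cluster's reference cells); compared datasets are
downsampled to equal depth before the prevalence-bias statistic (per-type
deviation from a 50/50 split, its standard deviation across types, and
the fraction of types with at least three-fold enrichment); donor-level
sex composition is tested per cluster with a Wilcoxon rank-sum on
per-donor cluster proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PrevalenceReport:
    """Per orthologous type, counts/proportions per dataset plus summaries."""

    table: pd.DataFrame  # index type; columns n_a, n_b, prop_a, deviation, fold
    stdev_deviation: float  # signed deviations, n-1 denominator (% points)
    frac_threefold: float  # fraction of types with fold >= 3 (either direction)
    stdev_deviation_abs: float  # |deviation| variant, for transparency
    frac_threefold_vs_a: float  # enrichment toward dataset a only


def transfer_majority_labels(
    joint_labels, reference_cell_mask, prior_labels
) -> pd.DataFrame:
    """Name each joint cluster by the majority prior label of its reference cells.

    A name is assigned iff strictly more than half of the cluster's
    reference cells carry it; otherwise the cluster keeps the placeholder
    ``JC-<k>``.  Returns a table indexed by joint cluster with columns
    ``name``, ``basis`` (winning share) and ``placeholder``.
    """
    joint_labels = np.asarray(joint_labels)
    reference_cell_mask = np.asarray(reference_cell_mask, dtype=bool)
    prior_labels = np.asarray(prior_labels, dtype=object)

    rows = []
    for cl in pd.unique(joint_labels):
        in_cl = joint_labels == cl
        ref = in_cl & reference_cell_mask
        n_ref = int(ref.sum())
        if n_ref == 0:
            rows.append({"joint_cluster": cl, "name": f"JC-{cl}",
                         "basis": 0.0, "placeholder": True})
            continue
        counts = pd.Series(prior_labels[ref]).value_counts()
        share = counts.iloc[0] / n_ref
        if share > 0.5:
            rows.append({"joint_cluster": cl, "name": counts.index[0],
                         "basis": float(share), "placeholder": False})
        else:
            rows.append({"joint_cluster": cl, "name": f"JC-{cl}",
                         "basis": float(share), "placeholder": True})
    return pd.DataFrame(rows).set_index("joint_cluster")


def equal_depth_subsample(
    a_cells, b_cells, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample the larger index set uniformly (without replacement) to the smaller's size."""
    a_cells = np.asarray(a_cells)
    b_cells = np.asarray(b_cells)
    if len(a_cells) == 0 or len(b_cells) == 0:
        raise ValueError("both cell sets must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(a_cells), len(b_cells))
    if len(a_cells) > n:
        a_cells = a_cells[np.sort(rng.choice(len(a_cells), size=n, replace=False))]
    elif len(b_cells) > n:
        b_cells = b_cells[np.sort(rng.choice(len(b_cells), size=n, replace=False))]
    return a_cells, b_cells


def prevalence_bias(type_of_cell, dataset_of_cell) -> PrevalenceReport:
    """Per-type deviation from an equal split between two equal-depth datasets.

    For each type, ``prop_a`` is the percentage of its pooled cells coming
    from the first dataset; ``deviation = prop_a - 50`` percentage points;
    ``fold`` is the larger proportion over the smaller (infinite when one
    side is absent, counted as three-fold enriched).  Summary statistics:
    standard deviation of the signed deviations (n-1 denominator) and the
    fraction of types at least three-fold enriched in either direction.
    """
    type_of_cell = pd.Series(np.asarray(type_of_cell, dtype=object))
    dataset_of_cell = pd.Series(np.asarray(dataset_of_cell, dtype=object))
    datasets = pd.unique(dataset_of_cell)
    if len(datasets) != 2:
        raise ValueError(f"expected exactly two datasets, got {list(datasets)}")
    ds_a, ds_b = datasets[0], datasets[1]

    tab = pd.crosstab(type_of_cell.rename("type"), dataset_of_cell.rename("dataset"))
    empty = tab.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"types with zero cells dropped: {tab.index[empty].tolist()}")
        tab = tab.loc[~empty]

    n_a = tab.get(ds_a, pd.Series(0, index=tab.index)).astype(int)
    n_b = tab.get(ds_b, pd.Series(0, index=tab.index)).astype(int)
    prop_a = 100.0 * n_a / (n_a + n_b)
    prop_b = 100.0 - prop_a
    deviation = prop_a - 50.0
    with np.errstate(divide="ignore"):
        fold = np.maximum(prop_a, prop_b) / np.minimum(prop_a, prop_b)

    table = pd.DataFrame(
        {"n_a": n_a, "n_b": n_b, "prop_a": prop_a,
         "deviation": deviation, "fold": fold}
    )
    threefold = (table["fold"] >= 3.0) | np.isinf(table["fold"])
    toward_a = threefold & (table["deviation"] > 0)
    return PrevalenceReport(
        table=table,
        stdev_deviation=float(np.std(deviation, ddof=1)) if len(table) > 1 else 0.0,
        frac_threefold=float(threefold.mean()),
        stdev_deviation_abs=float(np.std(np.abs(deviation), ddof=1)) if len(table) > 1 else 0.0,
        frac_threefold_vs_a=float(toward_a.mean()),
    )


def donor_composition_test(
    cluster_of_cell, donor_of_cell, sex_of_donor: dict | pd.Series
) -> pd.DataFrame:
    """Per-cluster Wilcoxon rank-sum of female vs male per-donor proportions.

    Each donor contributes the percentage of its cells assigned to the
    cluster (normalizing for donors' total cell counts).  The two-sided
    rank-sum test uses the exact null distribution when both sexes have at
    most 10 donors, and the normal approximation with continuity
    correction otherwise.  Returns mean % per sex, the rank-sum statistic
    W, the raw two-sided p (primary) and a Benjamini-Hochberg column.
    """
    cluster_of_cell = pd.Series(np.asarray(cluster_of_cell, dtype=object))
    donor_of_cell = pd.Series(np.asarray(donor_of_cell, dtype=object))
    sex_of_donor = pd.Series(sex_of_donor)

    donors = pd.unique(donor_of_cell)
    sexes = sex_of_donor.loc[donors]
    f_donors = [d for d in donors if sexes[d] == "F"]
    m_donors = [d for d in donors if sexes[d] == "M"]
    degenerate = len(f_donors) < 2 or len(m_donors) < 2
    if degenerate:
        warnings.warn("fewer than 2 donors in one sex; p-values undefined")

    totals = donor_of_cell.value_counts()
    tab = pd.crosstab(cluster_of_cell, donor_of_cell)
    prop = 100.0 * tab.div(totals, axis=1).reindex(columns=donors).fillna(0.0)

    exact = len(f_donors) <= 10 and len(m_donors) <= 10
    rows = []
    for cl in prop.index:
        f = prop.loc[cl, f_donors].to_numpy(dtype=float)
        m = prop.loc[cl, m_donors].to_numpy(dtype=float)
        if degenerate:
            w, p = np.nan, np.nan
        else:
            combined = np.concatenate([f, m])
            has_ties = len(np.unique(combined)) < len(combined)
            res = stats.mannwhitneyu(
                f, m, alternative="two-sided",
                method="exact" if (exact and not has_ties) else "asymptotic",
            )
            w, p = float(res.statistic), float(res.pvalue)
        rows.append({"cluster": cl, "mean_pct_f": float(f.mean()),
                     "mean_pct_m": float(m.mean()), "W": w, "p": p})
    out = pd.DataFrame(rows).set_index("cluster")
    if not degenerate and len(out):
        _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["p_adj"] = p_adj
    else:
        out["p_adj"] = np.nan
    return out
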