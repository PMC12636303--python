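"""Cell-surface gene conservation across datasets.

Builds a panel of variably expressed surface genes (union over datasets
of the top-N variable-feature ranking intersected with a surface-protein
list), computes per-type normalized pseudobulk profiles (summed raw
counts over the type's cells divided by the cell count), and quantifies
cross-dataset conservation as a per-type Spearman rank correlation over
the panel, compared between dataset pairs with an unpaired t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CountAtlas
from .features import select_variable_features


def variable_surface_panel(
    datasets: list[CountAtlas], surface_list, top_n: int = 200
) -> list[str]:
    """Union over datasets of (top-``top_n`` variable genes ∩ surface list)."""
    surface = set(surface_list)
    if not surface:
        raise ValueError("surface list is empty")
    panel: set = set()
    for atlas in datasets:
        top = select_variable_features(atlas, top_n).index
        panel |= set(top) & surface
    if not panel:
        raise ValueError("no variable surface genes found in any dataset")
    return sorted(panel)


def pseudobulk(atlas: CountAtlas, type_of_cell) -> pd.DataFrame:
    """types x genes matrix: summed raw counts per type / number of cells of the type.

    Types with zero cells are absent from the output.
    """
    type_of_cell = np.asarray(type_of_cell, dtype=object)
    if len(type_of_cell) != atlas.n_cells:
        raise ValueError("type_of_cell must label every cell")
    rows = {}
    for t in pd.unique(type_of_cell):
        mask = type_of_cell == t
        total = np.asarray(atlas.counts[:, mask].sum(axis=1)).ravel()
        rows[t] = total / mask.sum()
    pb = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    pb.columns = atlas.genes.index
    pb["n_cells"] = [int((type_of_cell == t).sum()) for t in pb.index]
    n = pb.pop("n_cells")
    pb.attrs["n_cells"] = n.to_dict()
    return pb


def conservation_correlations(
    pb_a: pd.DataFrame, pb_b: pd.DataFrame, panel, shared_types
) -> pd.Series:
    """Per shared type, Spearman rho between panel-restricted pseudobulk rows.

    Ties take average ranks.  A constant row makes rho undefined for that
    type (reported as NaN).
    """
    panel = list(panel)
    if len(panel) < 3:
        raise ValueError("panel must contain at least 3 genes")
    for pb, name in ((pb_a, "a"), (pb_b, "b")):
        missing = set(panel) - set(pb.columns)
        if missing:
            raise ValueError(f"panel genes missing from pseudobulk {name}: {sorted(missing)[:5]}")
    out = {}
    for t in shared_types:
        if t not in pb_a.index or t not in pb_b.index:
            raise ValueError(f"type {t!r} missing from a pseudobulk matrix")
        x = pb_a.loc[t, panel].to_numpy(dtype=float)
        y = pb_b.loc[t, panel].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[t] = np.nan
            continue
        rho, _ = stats.spearmanr(x, y)
        out[t] = float(rho)
    return pd.Series(out, name="spearman_rho")


def compare_conservation(rhos_1, rhos_2) -> dict:
    """Welch unpaired two-tailed t-test between two per-type rho vectors.

    Missing values are dropped independently in each vector.  The Student
    (equal-variance) p is also reported for transparency.
    """
    r1 = pd.Series(rhos_1).dropna().to_numpy(dtype=float)
    r2 = pd.Series(rhos_2).dropna().to_numpy(dtype=float)
    if len(r1) < 2 or len(r2) < 2:
        raise ValueError("each rho vector needs at least 2 non-missing values")
    welch = stats.ttest_ind(r1, r2, equal_var=False)
    student = stats.ttest_ind(r1, r2, equal_var=True)
    return {
        "mean_1": float(r1.mean()),
        "sd_1": float(r1.std(ddof=1)),
        "mean_2": float(r2.mean()),
        "sd_2": float(r2.std(ddof=1)),
        "t": float(welch.statistic),
        "p": float(welch.pvalue),
        "t_student": float(student.statistic),
        "p_student": float(student.pvalue),
        "n_1": int(len(r1)),
        "n_2": int(len(r2)),
    }
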