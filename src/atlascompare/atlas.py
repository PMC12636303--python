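"""Core in-memory containers shared by every pipeline stage.

A :class:`CountAtlas` holds a sparse genes-by-cells raw count matrix next to
a gene table and a cell-metadata table, plus optional derived expression
layers (``normalized``, ``scaled``).  Genes index rows throughout the
package; all file writers emit genes x cells, matching the MatrixMarket
convention of 10x-style triplet directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MITO_PREFIXES = ("MT-", "mt-")

REQUIRED_CELL_COLUMNS = ("donor", "sex", "dataset")
METADATA_SENTINEL = "unknown"


@dataclass
class CountAtlas:
    """Sparse non-negative integer count matrix with gene and cell tables.

    Parameters
    ----------
    counts
        genes x cells sparse matrix of raw counts (integral, >= 0).
    genes
        DataFrame indexed by unique gene id with at least columns
        ``symbol`` and ``is_mito``.
    cells
        DataFrame indexed by unique cell id with at least columns
        ``donor``, ``sex`` and ``dataset`` (missing metadata is filled with
        the sentinel ``"unknown"``).
    layers
        Optional derived matrices aligned to ``counts`` (``normalized``:
        real >= 0 sparse; ``scaled``: dense real over a feature subset, with
        its own row index in ``layers_genes``).
    """

    counts: sp.spmatrix
    genes: pd.DataFrame
    cells: pd.DataFrame
    layers: dict = field(default_factory=dict)
    layers_genes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.genes.index.duplicated().any():
            dups = self.genes.index[self.genes.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.cells.index.duplicated().any():
            dups = self.cells.index[self.cells.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell ids: {dups[:5]}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if "symbol" not in self.genes.columns:
            self.genes = self.genes.assign(symbol=self.genes.index)
        if "is_mito" not in self.genes.columns:
            self.genes = self.genes.assign(
                is_mito=self.genes["symbol"].astype(str).str.startswith(MITO_PREFIXES)
            )
        for col in REQUIRED_CELL_COLUMNS:
            if col not in self.cells.columns:
                self.cells = self.cells.assign(**{col: METADATA_SENTINEL})

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes.index.to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells.index.to_numpy()

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of counts in mitochondrial genes, per cell (0 for empty cells)."""
        lib = self.library_sizes().astype(float)
        mito = np.asarray(
            self.counts[self.genes["is_mito"].to_numpy(), :].sum(axis=0)
        ).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
        return frac

    # -- subsetting ------------------------------------------------------
    def subset(self, gene_mask=None, cell_mask=None) -> "CountAtlas":
        """Return a new atlas restricted to the given boolean/integer masks.

        Derived layers are propagated when their gene index survives the
        subset unchanged; otherwise they are dropped (they must be
        recomputed after a gene-space change).
        """
        gi = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        ci = np.arange(self.n_cells) if cell_mask is None else np.asarray(cell_mask)
        if gi.dtype == bool:
            gi = np.flatnonzero(gi)
        if ci.dtype == bool:
            ci = np.flatnonzero(ci)
        layers = {}
        layers_genes = {}
        genes_unchanged = gene_mask is None or (
            len(gi) == self.n_genes and np.array_equal(gi, np.arange(self.n_genes))
        )
        for name, layer in self.layers.items():
            lg = self.layers_genes.get(name)
            if lg is None:
                if genes_unchanged:
                    layers[name] = layer[:, ci]
                else:
                    layers[name] = layer[gi, :][:, ci]
            else:
                # feature-subset layer: keep as-is over the surviving cells
                layers[name] = layer[:, ci]
                layers_genes[name] = lg
        return CountAtlas(
            counts=self.counts[gi, :][:, ci],
            genes=self.genes.iloc[gi].copy(),
            cells=self.cells.iloc[ci].copy(),
            layers=layers,
            layers_genes=layers_genes,
        )

    def copy(self) -> "CountAtlas":
        return CountAtlas(
            counts=self.counts.copy(),
            genes=self.genes.copy(),
            cells=self.cells.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
            layers_genes={k: np.array(v) for k, v in self.layers_genes.items()},
        )


def concat_atlases(atlases: list[CountAtlas]) -> CountAtlas:
    """Column-concatenate atlases sharing an identical gene order."""
    first = atlases[0]
    for a in atlases[1:]:
        if not np.array_equal(a.gene_ids, first.gene_ids):
            raise ValueError("atlases must share an identical gene order")
    counts = sp.hstack([a.counts for a in atlases], format="csr")
    cells = pd.concat([a.cells for a in atlases], axis=0)
    out = CountAtlas(counts=counts, genes=first.genes.copy(), cells=cells)
    shared = set.intersection(*(set(a.layers) for a in atlases)) if atlases else set()
    for name in shared:
        if any(name in a.layers_genes for a in atlases):
            continue
        mats = [a.layers[name] for a in atlases]
        if all(sp.issparse(m) for m in mats):
            out.layers[name] = sp.hstack(mats, format="csr")
        else:
            out.layers[name] = np.hstack([np.asarray(m.todense()) if sp.issparse(m) else m for m in mats])
    return out
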