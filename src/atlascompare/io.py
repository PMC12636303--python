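"""Reading and writing 10x-style MatrixMarket triplet directories.

Layout per dataset directory::

    matrix.mtx      MatrixMarket coordinate file, genes x cells, integer
    features.tsv    gene_id <TAB> symbol
    barcodes.tsv    one cell id per line
    metadata.tsv    headered table with cell_id plus donor/sex/dataset/...

The metadata table is optional; missing columns are filled with the
sentinel ``"unknown"``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .atlas import METADATA_SENTINEL, REQUIRED_CELL_COLUMNS, CountAtlas


class FormatError(ValueError):
    """Raised when a triplet directory is internally inconsistent."""


def write_tenx_triplet(atlas: CountAtlas, directory: str | os.PathLike) -> None:
    """Write an atlas as a MatrixMarket triplet directory.

    Round-trips losslessly through :func:`read_tenx_triplet`.
    """
    if atlas.n_genes == 0 or atlas.n_cells == 0:
        raise ValueError("refusing to write an empty atlas")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(atlas.counts)
    scipy.io.mmwrite(str(d / "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame(
        {"gene_id": atlas.gene_ids, "symbol": atlas.genes["symbol"].to_numpy()}
    )
    feats.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    with open(d / "barcodes.tsv", "w") as fh:
        for cid in atlas.cell_ids:
            fh.write(f"{cid}\n")
    meta = atlas.cells.reset_index(names="cell_id")
    meta.to_csv(d / "metadata.tsv", sep="\t", index=False)


def read_tenx_triplet(directory: str | os.PathLike) -> CountAtlas:
    """Read a triplet directory into a :class:`CountAtlas`.

    ``is_mito`` is set from the gene symbol prefix (``MT-`` human, ``mt-``
    mouse).  Missing metadata columns are filled with ``"unknown"``.
    """
    d = Path(directory)
    mtx_path = d / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(f"no matrix.mtx in {d}")
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))

    feats = pd.read_csv(d / "features.tsv", sep="\t", header=None, dtype=str)
    if feats.shape[1] == 1:
        feats["symbol"] = feats[0]
    feats.columns = ["gene_id", "symbol"] + [f"extra{i}" for i in range(feats.shape[1] - 2)]
    if feats["gene_id"].duplicated().any():
        dup = feats.loc[feats["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"features.tsv: duplicate gene id {dup!r}")

    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None, dtype=str)[0]
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise FormatError(f"barcodes.tsv: duplicate cell id {dup!r}")

    if counts.shape[0] != len(feats):
        raise FormatError(
            f"matrix.mtx has {counts.shape[0]} rows but features.tsv "
            f"lists {len(feats)} genes"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix.mtx has {counts.shape[1]} columns but barcodes.tsv "
            f"lists {len(barcodes)} cells"
        )

    genes = feats.set_index("gene_id")[["symbol"]]
    cells = pd.DataFrame(index=pd.Index(barcodes.to_numpy(), name="cell_id"))

    meta_path = d / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise FormatError("metadata.tsv: missing cell_id column")
        meta = meta.set_index("cell_id")
        missing = set(cells.index) - set(meta.index)
        if missing:
            raise FormatError(
                f"metadata.tsv: {len(missing)} barcodes missing, e.g. "
                f"{sorted(missing)[:3]}"
            )
        cells = meta.reindex(cells.index)
    for col in REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            cells[col] = METADATA_SENTINEL
        else:
            cells[col] = cells[col].fillna(METADATA_SENTINEL)

    return CountAtlas(counts=counts, genes=genes, cells=cells)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a one-symbol-per-line gene list; '#' starts a comment."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_gene_list(genes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
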