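"""Cross-species gene-identifier harmonization.

Mouse-to-human (or any source-to-target) gene mapping through a
two-column ortholog table.  Genes with no ortholog, with several target
orthologs, or whose target is claimed by several sources are excluded;
only clean one-to-one pairs are renamed into the target namespace, after
which paired atlases are restricted to their shared gene space.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import CountAtlas

CLASSES = ("one_to_one", "one_to_many", "many_to_one", "unmapped")


@dataclass
class OrthologTable:
    """Cross-species gene pairs (``source_gene``, ``target_gene``)."""

    pairs: pd.DataFrame
    planted_class: pd.Series | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        cols = {"source_gene", "target_gene"}
        if not cols.issubset(self.pairs.columns):
            raise ValueError(f"ortholog table needs columns {sorted(cols)}")
        self.pairs = self.pairs[["source_gene", "target_gene"]].drop_duplicates()

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "OrthologTable":
        return cls(pairs=pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def classify_mappings(
    table: OrthologTable, source_universe, target_universe
) -> pd.Series:
    """Classify every source gene as one_to_one / one_to_many / many_to_one / unmapped.

    A source gene with more than one target is one_to_many.  A target gene
    claimed by more than one source makes *all* its sources many_to_one
    (ambiguous; excluded downstream).  Source genes absent from the table
    are unmapped.  Classification is total over ``source_universe``.
    """
    source_universe = pd.Index(source_universe)
    target_universe = pd.Index(target_universe)
    if len(source_universe) == 0 or len(target_universe) == 0:
        raise ValueError("universes must be non-empty")
    pairs = table.pairs[
        table.pairs["source_gene"].isin(source_universe)
        & table.pairs["target_gene"].isin(target_universe)
    ]
    src_counts = pairs["source_gene"].value_counts()
    tgt_counts = pairs["target_gene"].value_counts()
    ambiguous_targets = set(tgt_counts.index[tgt_counts > 1])

    cls = pd.Series("unmapped", index=source_universe, dtype=object)
    for src, grp in pairs.groupby("source_gene"):
        if len(grp) > 1:
            cls[src] = "one_to_many"
        elif grp["target_gene"].iloc[0] in ambiguous_targets:
            cls[src] = "many_to_one"
        else:
            cls[src] = "one_to_one"
    return cls


def harmonize(atlas: CountAtlas, table: OrthologTable) -> tuple[CountAtlas, pd.Series]:
    """Rename the atlas into the target namespace; keep only one_to_one genes.

    Returns the renamed atlas and an exclusion report: per-class gene
    counts (retained = one_to_one).  Counts are untouched.
    """
    if atlas.n_genes == 0:
        return atlas.copy(), pd.Series({c: 0 for c in CLASSES}, name="n_genes")
    targets = pd.Index(table.pairs["target_gene"].unique())
    if len(targets) == 0:
        cls = pd.Series("unmapped", index=atlas.genes.index, dtype=object)
    else:
        cls = classify_mappings(table, atlas.genes.index, targets)
    report = cls.value_counts().reindex(CLASSES, fill_value=0).rename("n_genes")

    keep = cls == "one_to_one"
    sub = atlas.subset(gene_mask=keep.to_numpy())
    mapping = (
        table.pairs.set_index("source_gene")["target_gene"]
        .loc[sub.genes.index]
    )
    if mapping.duplicated().any():
        raise RuntimeError("renaming collision among one_to_one genes")
    genes = sub.genes.copy()
    genes.index = pd.Index(mapping.to_numpy(), name="gene_id")
    genes["symbol"] = genes.index
    sub.genes = genes
    return sub, report


def shared_gene_space(
    a: CountAtlas, b: CountAtlas
) -> tuple[CountAtlas, CountAtlas, int]:
    """Restrict both atlases to the symbol intersection, identically ordered."""
    shared = a.genes.index.intersection(b.genes.index).sort_values()
    if len(shared) == 0:
        raise ValueError("no shared genes between atlases")
    ia = a.genes.index.get_indexer(shared)
    ib = b.genes.index.get_indexer(shared)
    return a.subset(gene_mask=ia), b.subset(gene_mask=ib), len(shared)
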