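import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlascompare.atlas import CountAtlas
from atlascompare.qc import QcThresholds, filter_qc, lognormalize
from atlascompare.simgen import SimConfig, simulate_atlas

TINY_QC = QcThresholds(min_features_create=50, min_features_subset=100)


def _make_atlas(counts, gene_ids=None, cell_ids=None, **cell_cols) -> CountAtlas:
    """Build a CountAtlas from a dense array (genes x cells) for hand-made cases."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{j}" for j in range(n_cells)]
    genes = pd.DataFrame({"symbol": gene_ids}, index=pd.Index(gene_ids, name="gene_id"))
    cells = pd.DataFrame(cell_cols, index=pd.Index(cell_ids, name="cell_id"))
    return CountAtlas(counts=sp.csr_matrix(counts), genes=genes, cells=cells)


@pytest.fixture(scope="session")
def make_atlas():
    """Factory fixture: build a CountAtlas from a dense genes x cells array."""
    return _make_atlas


@pytest.fixture(scope="session")
def sim_pair():
    """A moderate two-dataset simulation with well-separated types, QC'd and normalized."""
    cfg = SimConfig(
        cells_per_dataset=(500, 500), n_genes=600, n_types=4,
        markers_per_type=10, marker_log2fc=3.0, seed=11,
    )
    atlases, truth = simulate_atlas(cfg)
    prepared = []
    for a in atlases:
        f, _ = filter_qc(a, TINY_QC)
        prepared.append(lognormalize(f))
    return cfg, prepared, truth


@pytest.fixture(scope="session")
def null_atlas():
    """A single-type (null) atlas: no marker structure, one population."""
    cfg = SimConfig(
        cells_per_dataset=(600, 100), n_genes=500, n_types=1,
        markers_per_type=0, marker_log2fc=0.0, seed=7,
    )
    atlases, _ = simulate_atlas(cfg)
    a, _ = filter_qc(atlases[0], TINY_QC)
    return lognormalize(a)
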