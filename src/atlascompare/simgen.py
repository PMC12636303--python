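"""Synthetic multi-dataset atlas generator with known ground truth.

Emulates the statistical structure of single-nucleus RNA-seq count data:
negative-binomial counts with per-type marker structure, lognormal library
sizes, donor/sex/dataset covariates, mitochondrial and cell-surface gene
classes, planted cross-dataset proportion shifts and surface-gene
divergence, plus an ortholog table mixing one-to-one, one-to-many and
unmapped entries and a spatial transcript table with planted population
membership.  Every downstream stage of the pipeline is testable offline
against the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas import CountAtlas
from .io import write_tenx_triplet  # noqa: F401  (re-exported: part of this module's surface)
from .orthology import OrthologTable

LN2 = math.log(2.0)


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas world.

    Defaults describe a small but realistic two-dataset comparison: 2,000
    cells per dataset, 1,000 genes, 8 neuron-like types with 10 markers
    each at 2 log2-fold over baseline, NB dispersion 2 (strong
    overdispersion, typical of snRNA-seq), median library ~5,000 counts
    with 0.35 log-sd, 2% mitochondrial genes at baseline expression
    (nuclear preparations carry little mitochondrial RNA), 15% surface
    genes.
    """

    n_datasets: int = 2
    cells_per_dataset: tuple = (2000, 2000)
    n_genes: int = 1000
    n_types: int = 8
    type_proportions: tuple | None = None  # per-dataset vectors; default uniform
    base_log_mean: object = None  # None -> N(0,1) per gene; scalar or per-gene array
    marker_log2fc: float = 2.0
    markers_per_type: int = 10
    nb_dispersion: float = 2.0
    libsize_log_mean: float = math.log(5000.0)
    libsize_log_sd: float = 0.35
    mito_gene_fraction: float = 0.02
    mito_expression_boost: float = 0.0
    surface_gene_fraction: float = 0.15
    surface_divergence_sd: float = 0.0
    ortholog_one_to_many_fraction: float = 0.05
    ortholog_unmapped_fraction: float = 0.10
    n_donors_per_dataset: int = 4
    donor_libsize_sd: float = 0.0
    female_only_types: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets: must be positive")
        if len(self.cells_per_dataset) != self.n_datasets:
            raise ValueError("cells_per_dataset: need one count per dataset")
        if any(c < 1 for c in self.cells_per_dataset):
            raise ValueError("cells_per_dataset: all counts must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes: must be positive")
        if self.n_types < 1:
            raise ValueError("n_types: must be positive")
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc: must be >= 0")
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type: must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion: must be > 0")
        for name in ("mito_gene_fraction", "surface_gene_fraction",
                     "ortholog_one_to_many_fraction", "ortholog_unmapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1]")
        if self.mito_gene_fraction + self.surface_gene_fraction > 1.0:
            raise ValueError("mito_gene_fraction: mito + surface fractions exceed 1")
        if self.ortholog_one_to_many_fraction + self.ortholog_unmapped_fraction > 1.0:
            raise ValueError("ortholog_unmapped_fraction: ortholog fractions sum above 1")
        if self.mito_expression_boost < 0:
            raise ValueError("mito_expression_boost: must be >= 0")
        if self.surface_divergence_sd < 0:
            raise ValueError("surface_divergence_sd: must be >= 0")
        if self.n_donors_per_dataset < 4:
            raise ValueError("n_donors_per_dataset: must be >= 4")
        props = self.resolved_proportions()
        for d, p in enumerate(props):
            if len(p) != self.n_types:
                raise ValueError("type_proportions: wrong length for dataset %d" % d)
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError("type_proportions: dataset %d vector does not sum to 1" % d)
            if np.any(np.asarray(p) < 0):
                raise ValueError("type_proportions: negative entry in dataset %d" % d)
        if any(t < 0 or t >= self.n_types for t in self.female_only_types):
            raise ValueError("female_only_types: type index out of range")

    def resolved_proportions(self) -> list[np.ndarray]:
        if self.type_proportions is None:
            return [np.full(self.n_types, 1.0 / self.n_types)
                    for _ in range(self.n_datasets)]
        return [np.asarray(p, dtype=float) for p in self.type_proportions]


@dataclass
class GroundTruth:
    """Planted truth of a simulated atlas."""

    cell_type: pd.Series  # per cell (all datasets), type name
    gene_role: pd.Series  # per gene: marker:<type>, mitochondrial, surface, housekeeping
    planted_prevalence_deviation: pd.Series  # per type, % points vs 50/50 (datasets 0 vs 1)
    marker_genes: dict = field(default_factory=dict)  # type name -> list of gene ids
    ortholog_class: pd.Series | None = None


def type_name(k: int) -> str:
    return f"T{k:02d}"


def _assign_gene_roles(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_genes
    n_mito = int(round(cfg.mito_gene_fraction * n))
    n_surface = int(round(cfg.surface_gene_fraction * n))
    perm = rng.permutation(n)
    mito_idx = np.sort(perm[:n_mito])
    rest = perm[n_mito:]
    n_marker = min(cfg.markers_per_type * cfg.n_types, len(rest) - n_surface)
    n_marker = max(n_marker, 0)
    marker_pool = np.sort(rest[:n_marker])
    surface_idx = np.sort(rest[n_marker:n_marker + n_surface])

    role = np.full(n, "housekeeping", dtype=object)
    role[mito_idx] = "mitochondrial"
    role[surface_idx] = "surface"
    marker_of = {}
    per_type = n_marker // cfg.n_types if cfg.n_types else 0
    for k in range(cfg.n_types):
        sel = marker_pool[k * per_type:(k + 1) * per_type]
        marker_of[type_name(k)] = sel
        role[sel] = f"marker:{type_name(k)}"
    return role, marker_of, mito_idx, surface_idx


def simulate_atlas(cfg: SimConfig) -> tuple[list[CountAtlas], GroundTruth]:
    """Simulate one :class:`CountAtlas` per dataset plus the planted truth.

    Counts are negative-binomial (gamma–Poisson) with per-cell mean
    ``libsize * p[gene, type]`` where the relative-expression vector ``p``
    is a normalized exponential of per-gene log-means: baseline plus
    ``ln(2) * marker_log2fc`` for a type's markers, a mitochondrial boost,
    and per-dataset Gaussian jitter on surface genes (the planted
    conservation divergence).  Cells are partitioned round-robin into
    donors; donors alternate F/M; types listed in ``female_only_types``
    have probability zero in male donors.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    if cfg.base_log_mean is None:
        base = rng.normal(0.0, 1.0, size=cfg.n_genes)
    else:
        base = np.broadcast_to(np.asarray(cfg.base_log_mean, dtype=float),
                               (cfg.n_genes,)).copy()

    role, marker_of, mito_idx, _surface_idx = _assign_gene_roles(cfg, rng)
    is_mito = np.zeros(cfg.n_genes, dtype=bool)
    is_mito[mito_idx] = True
    is_surface = role == "surface"

    gene_ids = np.array(
        [f"MT-G{i:05d}" if is_mito[i] else f"G{i:05d}" for i in range(cfg.n_genes)]
    )
    genes = pd.DataFrame(
        {"symbol": gene_ids, "is_mito": is_mito, "role": role},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # per-type log-mean matrix (genes x types), shared across datasets
    logmu = np.tile(base[:, None], (1, cfg.n_types))
    for k in range(cfg.n_types):
        logmu[marker_of[type_name(k)], k] += LN2 * cfg.marker_log2fc
    logmu[is_mito, :] += cfg.mito_expression_boost

    props = cfg.resolved_proportions()
    type_names = [type_name(k) for k in range(cfg.n_types)]
    atlases = []
    truth_type = {}

    for d in range(cfg.n_datasets):
        ds = f"ds{chr(ord('A') + d)}"
        n_cells = int(cfg.cells_per_dataset[d])
        jitter = np.zeros(cfg.n_genes)
        if cfg.surface_divergence_sd > 0:
            jitter[is_surface] = rng.normal(0.0, cfg.surface_divergence_sd,
                                            size=int(is_surface.sum()))
        rel = np.exp(logmu + jitter[:, None])
        rel /= rel.sum(axis=0, keepdims=True)  # relative expression per type

        donor_idx = np.arange(n_cells) % cfg.n_donors_per_dataset
        donor_sex = np.array(["F" if j % 2 == 0 else "M"
                              for j in range(cfg.n_donors_per_dataset)])
        sex = donor_sex[donor_idx]

        p_f = props[d].copy()
        p_m = props[d].copy()
        for t in cfg.female_only_types:
            p_m[t] = 0.0
        if p_m.sum() == 0:
            raise ValueError("female_only_types: no type left for male donors")
        p_m = p_m / p_m.sum()
        types = np.empty(n_cells, dtype=int)
        f_mask = sex == "F"
        types[f_mask] = rng.choice(cfg.n_types, size=int(f_mask.sum()), p=p_f)
        types[~f_mask] = rng.choice(cfg.n_types, size=int((~f_mask).sum()), p=p_m)

        lib_mu = cfg.libsize_log_mean + (
            rng.normal(0.0, cfg.donor_libsize_sd, size=cfg.n_donors_per_dataset)
            if cfg.donor_libsize_sd > 0 else np.zeros(cfg.n_donors_per_dataset)
        )
        libsize = rng.lognormal(mean=lib_mu[donor_idx], sigma=cfg.libsize_log_sd)

        mu = rel[:, types] * libsize[None, :]  # genes x cells
        theta = cfg.nb_dispersion
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = sp.csr_matrix(rng.poisson(lam))

        cell_ids = np.array([f"{ds}_c{i:06d}" for i in range(n_cells)])
        tnames = np.array(type_names, dtype=object)[types]
        cells = pd.DataFrame(
            {
                "donor": [f"{ds}_d{j}" for j in donor_idx],
                "sex": sex,
                "region": "other",
                "dataset": ds,
                "true_type": tnames,
                "prior_label": tnames,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
        atlases.append(CountAtlas(counts=counts, genes=genes.copy(), cells=cells))
        truth_type[ds] = pd.Series(tnames, index=cell_ids)

    cell_type = pd.concat(list(truth_type.values()))
    pA, pB = props[0], props[1] if cfg.n_datasets > 1 else props[0]
    with np.errstate(invalid="ignore"):
        dev = 100.0 * pA / np.where(pA + pB > 0, pA + pB, np.nan) - 50.0
    gt = GroundTruth(
        cell_type=cell_type,
        gene_role=pd.Series(role, index=gene_ids),
        planted_prevalence_deviation=pd.Series(dev, index=type_names),
        marker_genes={t: gene_ids[idx].tolist() for t, idx in marker_of.items()},
    )
    return atlases, gt


def simulate_ortholog_table(cfg: SimConfig, gene_ids) -> OrthologTable:
    """Build an ortholog table over ``gene_ids`` with planted mapping classes.

    Exact quotas: ``round(fraction * n)`` genes are left unmapped,
    ``round(fraction * n)`` map one-to-many (two targets); the remainder
    map one-to-one under the deterministic renaming ``g -> H-g``.  The
    planted class per source gene is recorded on the returned table.
    """
    cfg.validate()
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene ids must be unique")
    n = len(gene_ids)
    rng = np.random.default_rng(cfg.seed + 1)
    n_un = int(round(cfg.ortholog_unmapped_fraction * n))
    n_o2m = int(round(cfg.ortholog_one_to_many_fraction * n))
    perm = rng.permutation(n)
    unmapped = set(perm[:n_un])
    one_to_many = set(perm[n_un:n_un + n_o2m])

    rows = []
    classes = {}
    for i, g in enumerate(gene_ids):
        if i in unmapped:
            classes[g] = "unmapped"
            continue
        rows.append((g, f"H-{g}"))
        if i in one_to_many:
            rows.append((g, f"H-{g}-2"))
            classes[g] = "one_to_many"
        else:
            classes[g] = "one_to_one"
    pairs = pd.DataFrame(rows, columns=["source_gene", "target_gene"])
    table = OrthologTable(pairs=pairs)
    table.planted_class = pd.Series(classes, dtype=object) if classes else pd.Series(dtype=object)
    return table


def simulate_spatial_cells(
    cfg: SimConfig,
    panel_genes,
    populations: dict,
    n_cells: int = 1000,
    lam_high: float = 8.0,
    lam_low: float = 0.2,
    gate_gene: str = "RBFOX3",
    background_fraction: float = 0.3,
    extent: float = 1000.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a spatial transcript-count-per-cell table.

    Each cell is either background (no population) or a member of one
    population.  Members draw Poisson(``lam_high``) transcripts for their
    population's markers and the neuronal gate gene; all other panel genes
    (and all genes of background cells) draw Poisson(``lam_low``).
    Coordinates are uniform over an ``extent`` x ``extent`` square (um).

    Returns the table and the planted membership (population name or
    ``"none"`` per cell).
    """
    if lam_high <= lam_low:
        raise ValueError("lam_high must exceed lam_low")
    panel = list(panel_genes)
    if gate_gene not in panel:
        panel = [gate_gene] + panel
    for name, markers in populations.items():
        if not markers:
            raise ValueError(f"population {name!r} declares no marker genes")
        missing = [m for m in markers if m not in panel]
        if missing:
            raise ValueError(
                f"population {name!r} references genes absent from the panel: {missing}"
            )
    rng = np.random.default_rng(cfg.seed + 2)
    names = list(populations)
    cols = {g: j for j, g in enumerate(panel)}

    if n_cells == 0:
        table = pd.DataFrame(columns=["cell_id", "x", "y", *panel])
        return table, pd.Series(dtype=object)

    member = rng.random(n_cells) >= background_fraction
    assign = np.where(
        member & (len(names) > 0),
        rng.integers(0, max(len(names), 1), size=n_cells),
        -1,
    )
    lam = np.full((n_cells, len(panel)), lam_low, dtype=float)
    for k, name in enumerate(names):
        sel = assign == k
        for m in populations[name]:
            lam[sel, cols[m]] = lam_high
        lam[sel, cols[gate_gene]] = lam_high
    counts = rng.poisson(lam)
    xy = rng.uniform(0.0, extent, size=(n_cells, 2))
    cell_ids = [f"sp_c{i:06d}" for i in range(n_cells)]
    table = pd.DataFrame(counts, columns=panel)
    table.insert(0, "y", xy[:, 1])
    table.insert(0, "x", xy[:, 0])
    table.insert(0, "cell_id", cell_ids)
    membership = pd.Series(
        [names[a] if a >= 0 else "none" for a in assign], index=cell_ids
    )
    return table, membership
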