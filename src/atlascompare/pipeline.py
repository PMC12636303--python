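"""End-to-end pipeline over synthetic or on-disk atlases.

Ties the stages together: simulate -> QC -> ortholog harmonization ->
anchor integration + clustering -> majority labeling + prevalence ->
signature scoring -> surface conservation -> spatial gating.  Every stage
writes plain TSV/YAML so any stage can be inspected or replaced, and a
provenance manifest (config hash, package versions, seeds) makes a run
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import CountAtlas, concat_atlases
from .compare import (donor_composition_test, equal_depth_subsample,
                      prevalence_bias, transfer_majority_labels)
from .conservation import (compare_conservation, conservation_correlations,
                           pseudobulk, variable_surface_panel)
from .features import anchor_features
from .integrate import cluster_graph, find_anchors, find_markers, integrate_expression
from .io import read_tenx_triplet, write_gene_list, write_tenx_triplet
from .orthology import harmonize, shared_gene_space
from .qc import QcThresholds, filter_qc, lognormalize, scale_features
from .signatures import module_score, per_gene_group_de, score_group_test
from .simgen import (SimConfig, simulate_atlas, simulate_ortholog_table,
                     simulate_spatial_cells)
from .spatial import GateSpec, export_selection, gate_population

log = logging.getLogger("atlascompare")

PRESETS = {
    # per-dataset clustering conventions: 2000 vst features, anchors over
    # dims 1:10, 15 PCs, Leiden resolution 1
    "within_dataset": {
        "n_anchor_features": 2000, "dims": 10, "k_anchor": 5, "k_filter": 200,
        "k_score": 30, "n_pcs": 15, "k_neighbors": 20, "resolution": 1.0,
    },
    # cross-species conventions: top-7500 variable features per dataset for
    # anchors, 30 PCs, Leiden resolution 2
    "cross_species": {
        "n_anchor_features": 7500, "dims": 10, "k_anchor": 5, "k_filter": 200,
        "k_score": 30, "n_pcs": 30, "k_neighbors": 20, "resolution": 2.0,
    },
}

FIXTURE_SCALES = {
    "tiny": dict(cells_per_dataset=(200, 200), n_genes=300, n_types=4,
                 markers_per_type=8),
    "small": dict(cells_per_dataset=(3000, 3000), n_genes=2000, n_types=12,
                  markers_per_type=10),
}

# detected-gene counts scale with the simulated gene count, so the tiny
# fixture states proportionally smaller feature thresholds; "small" keeps
# the full-scale defaults (3 cells / 200 / 500 features / 5% mito)
FIXTURE_QC = {
    "tiny": dict(min_features_create=50, min_features_subset=100),
    "small": {},
}

_FLOAT_FMT = "%.6g"


@dataclasses.dataclass
class PipelineConfig:
    sim: SimConfig
    preset: str = "cross_species"
    qc: QcThresholds = dataclasses.field(default_factory=QcThresholds)
    seed: int = 0
    log_level: str = "INFO"
    signature_type: str = "T00"  # planted type whose markers form the signature set
    n_signature_genes: int = 25
    spatial_n_cells: int = 1000

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        self.sim.validate()
        self.qc.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["cells_per_dataset"] = list(d["sim"]["cells_per_dataset"])
        d["sim"]["female_only_types"] = list(d["sim"]["female_only_types"])
        if d["sim"]["type_proportions"] is not None:
            d["sim"]["type_proportions"] = [list(map(float, p)) for p in d["sim"]["type_proportions"]]
        if d["sim"]["base_log_mean"] is not None and not np.isscalar(d["sim"]["base_log_mean"]):
            d["sim"]["base_log_mean"] = [float(v) for v in np.asarray(d["sim"]["base_log_mean"]).ravel()]
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        if "cells_per_dataset" in sim:
            sim["cells_per_dataset"] = tuple(sim["cells_per_dataset"])
        if "type_proportions" in sim and sim["type_proportions"] is not None:
            sim["type_proportions"] = tuple(tuple(p) for p in sim["type_proportions"])
        if "female_only_types" in sim:
            sim["female_only_types"] = tuple(sim["female_only_types"])
        qc = d.pop("qc", {})
        return cls(sim=SimConfig(**sim), qc=QcThresholds(**qc), **d)


def _write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def make_fixtures(out_dir, scale: str = "tiny", seed: int = 0) -> PipelineConfig:
    """Write deterministic packaged test datasets (triplet dirs + truth)."""
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(FIXTURE_SCALES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = FIXTURE_SCALES[scale]
    n_types = params["n_types"]
    # planted proportion shifts between the two datasets, incl. one strong
    # (three-fold-scale) shift on the first type
    base = np.full(n_types, 1.0 / n_types)
    pa, pb = base.copy(), base.copy()
    pa[0] *= 1.5
    pb[0] *= 0.5
    pa[1] *= 0.75
    pb[1] *= 1.25
    pa /= pa.sum()
    pb /= pb.sum()
    sim = SimConfig(
        type_proportions=(tuple(pa), tuple(pb)),
        surface_divergence_sd=0.4,
        seed=seed,
        **params,
    )
    cfg = PipelineConfig(sim=sim, qc=QcThresholds(**FIXTURE_QC[scale]), seed=seed)
    cfg.validate()
    atlases, truth = simulate_atlas(sim)
    for atlas in atlases:
        ds = atlas.cells["dataset"].iloc[0]
        write_tenx_triplet(atlas, out / ds)
    truth.cell_type.rename("true_type").to_frame().to_csv(out / "truth_cell_type.tsv", sep="\t")
    truth.gene_role.rename("role").to_frame().to_csv(out / "truth_gene_role.tsv", sep="\t")
    cfg.to_yaml(out / "config.yaml")
    return cfg


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage on a synthetic atlas pair; return a result summary.

    Stage outputs land in ``out_dir`` as TSV/YAML; a provenance manifest
    (config hash, versions, seed) is written alongside.  A stage failure
    raises with the stage name while earlier outputs are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    preset = PRESETS[config.preset]
    seed = config.seed
    summary: dict = {}
    stage = "simulate"
    try:
        # -- simulate -----------------------------------------------------
        log.info("stage simulate")
        atlases, truth = simulate_atlas(config.sim)
        ds_names = [a.cells["dataset"].iloc[0] for a in atlases]
        for a in atlases:
            write_tenx_triplet(a, out / "sim" / a.cells["dataset"].iloc[0])
        config.to_yaml(out / "config.yaml")

        # -- qc ------------------------------------------------------------
        stage = "qc"
        log.info("stage qc")
        qc_atlases = []
        qc_reports = {}
        for a, name in zip(atlases, ds_names):
            filtered, report = filter_qc(a, config.qc)
            filtered = lognormalize(filtered)
            qc_atlases.append(filtered)
            qc_reports[name] = report
        _write_tsv(pd.DataFrame(qc_reports), out / "qc_report.tsv")

        # -- orthology ------------------------------------------------------
        stage = "orthology"
        log.info("stage orthology")
        table = simulate_ortholog_table(config.sim, atlases[0].genes.index)
        table.to_tsv(out / "orthologs.tsv")
        harmonized = []
        excl = {}
        for a, name in zip(qc_atlases, ds_names):
            h, report = harmonize(a, table)
            harmonized.append(h)
            excl[name] = report
        _write_tsv(pd.DataFrame(excl), out / "ortholog_exclusions.tsv")
        a_h, b_h, n_shared = shared_gene_space(harmonized[0], harmonized[1])
        summary["n_shared_genes"] = n_shared
        a_h = lognormalize(a_h)
        b_h = lognormalize(b_h)

        # -- integrate --------------------------------------------------------
        stage = "integrate"
        log.info("stage integrate")
        feats = anchor_features(a_h, b_h, preset["n_anchor_features"])
        a_s = scale_features(a_h, feats)
        b_s = scale_features(b_h, feats)
        anchors = find_anchors(
            a_s, b_s, feats, dims=preset["dims"], k_anchor=preset["k_anchor"],
            k_filter=preset["k_filter"], k_score=preset["k_score"],
        )
        summary["n_anchors"] = len(anchors.anchors)
        corrected, cell_index = integrate_expression(
            anchors, a_s, b_s, a_h.genes.index
        )
        labels = cluster_graph(
            corrected, n_pcs=preset["n_pcs"], k_neighbors=preset["k_neighbors"],
            resolution=preset["resolution"], seed=seed,
        )
        joint = pd.DataFrame({"cell_id": cell_index, "cluster": labels}).set_index("cell_id")
        _write_tsv(joint, out / "joint_clusters.tsv")
        combined = concat_atlases([a_s, b_s])
        markers = find_markers(combined, labels)
        _write_tsv(markers, out / "markers.tsv", index=False)
        summary["n_joint_clusters"] = int(len(np.unique(labels)))

        # -- compare -----------------------------------------------------------
        stage = "compare"
        log.info("stage compare")
        ref_mask = (combined.cells["dataset"] == ds_names[0]).to_numpy()
        label_map = transfer_majority_labels(
            labels, ref_mask, combined.cells["prior_label"].to_numpy()
        )
        _write_tsv(label_map, out / "label_map.tsv")
        named = label_map.loc[labels, "name"].to_numpy()
        idx_a = np.flatnonzero(ref_mask)
        idx_b = np.flatnonzero(~ref_mask)
        sub_a, sub_b = equal_depth_subsample(idx_a, idx_b, seed=seed)
        both = np.concatenate([sub_a, sub_b])
        prev = prevalence_bias(
            named[both], combined.cells["dataset"].to_numpy()[both]
        )
        _write_tsv(prev.table, out / "prevalence.tsv")
        with open(out / "prevalence_summary.yaml", "w") as fhh:
            yaml.safe_dump(
                {
                    "stdev_deviation": round(prev.stdev_deviation, 6),
                    "stdev_deviation_abs": round(prev.stdev_deviation_abs, 6),
                    "frac_threefold": round(prev.frac_threefold, 6),
                    "frac_threefold_vs_a": round(prev.frac_threefold_vs_a, 6),
                },
                fhh,
            )
        summary["prevalence_stdev"] = prev.stdev_deviation
        summary["frac_threefold"] = prev.frac_threefold

        donors_a = a_h.cells["donor"]
        sex_of_donor = a_h.cells.groupby("donor")["sex"].first()
        donor_tab = donor_composition_test(
            named[: a_h.n_cells], donors_a.to_numpy(), sex_of_donor
        )
        _write_tsv(donor_tab, out / "donor_composition.tsv")

        # -- score ----------------------------------------------------------------
        stage = "score"
        log.info("stage score")
        sig_type = config.signature_type
        sig_raw = truth.marker_genes.get(sig_type, [])[: config.n_signature_genes]
        # markers live in the harmonized namespace after orthology
        sig = [f"H-{g}" for g in sig_raw if f"H-{g}" in a_h.genes.index]
        score_summary = {}
        if sig:
            write_gene_list(sig, out / "signature_genes.txt")
            sc = module_score(a_h, sig, seed=seed)
            _write_tsv(sc.scores.rename("score").to_frame(), out / "signature_scores.tsv")
            group = (a_h.cells["true_type"] == sig_type).to_numpy()
            if group.any() and (~group).any():
                score_summary = score_group_test(sc, group)
                de = per_gene_group_de(a_h, group, sig)
                _write_tsv(de, out / "signature_de.tsv")
        with open(out / "score_summary.yaml", "w") as fhh:
            yaml.safe_dump({k: float(v) for k, v in score_summary.items()}, fhh)
        summary["score"] = score_summary

        # -- conserve ----------------------------------------------------------------
        stage = "conserve"
        log.info("stage conserve")
        surface_src = truth.gene_role.index[truth.gene_role == "surface"]
        surface = [f"H-{g}" for g in surface_src if f"H-{g}" in a_h.genes.index]
        panel = variable_surface_panel([a_h, b_h], surface, top_n=200)
        write_gene_list(panel, out / "surface_panel.txt")
        types_a = a_h.cells["true_type"].to_numpy()
        types_b = b_h.cells["true_type"].to_numpy()
        pb_a = pseudobulk(a_h, types_a)
        pb_b = pseudobulk(b_h, types_b)
        shared_types = sorted(set(pb_a.index) & set(pb_b.index))
        rho_cross = conservation_correlations(pb_a, pb_b, panel, shared_types)
        # within-dataset control: split-half pseudobulk of the first dataset
        rng = np.random.default_rng(seed)
        half = rng.random(a_h.n_cells) < 0.5
        pb_a1 = pseudobulk(a_h.subset(cell_mask=half), types_a[half])
        pb_a2 = pseudobulk(a_h.subset(cell_mask=~half), types_a[~half])
        within_types = sorted(set(pb_a1.index) & set(pb_a2.index))
        rho_within = conservation_correlations(pb_a1, pb_a2, panel, within_types)
        _write_tsv(
            pd.DataFrame({"cross_dataset": rho_cross, "within_dataset": rho_within}),
            out / "conservation_rho.tsv",
        )
        cons = compare_conservation(rho_within, rho_cross)
        with open(out / "conservation_summary.yaml", "w") as fhh:
            yaml.safe_dump({k: (float(v) if isinstance(v, float) else v)
                            for k, v in cons.items()}, fhh)
        summary["conservation"] = cons

        # -- gate ----------------------------------------------------------------
        stage = "gate"
        log.info("stage gate")
        panel_genes = ["RBFOX3", "MK1", "MK2", "MK3", "MK4"]
        pops = {"POP1": ["MK1", "MK2"], "POP2": ["MK3", "MK4"]}
        sp_table, membership = simulate_spatial_cells(
            config.sim, panel_genes, pops, n_cells=config.spatial_n_cells
        )
        sp_table.to_csv(out / "spatial_cells.csv", index=False, float_format=_FLOAT_FMT)
        selections = {}
        for name, mk in pops.items():
            spec = GateSpec(name=name, marker_genes=mk)
            selections[name] = gate_population(sp_table, spec, sex="F")
        gated = export_selection(sp_table, selections, out / "gated_cells.csv")
        summary["n_gated"] = int(len(gated))
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.as_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "preset": config.preset,
        "stages": ["simulate", "qc", "orthology", "integrate", "compare",
                   "score", "conserve", "gate"],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fhh:
        json.dump(manifest, fhh, indent=2, sort_keys=True)
    return summary
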