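"""Anchoring, expression correction, graph clustering, marker detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from atlascompare.atlas import concat_atlases
from atlascompare.features import anchor_features
from atlascompare.integrate import (cluster_graph, find_anchors, find_markers,
                                    integrate_expression,
                                    mutual_nearest_neighbors_bruteforce)
from atlascompare.qc import lognormalize, scale_features
from atlascompare.simgen import SimConfig, simulate_atlas


def prep_pair(sim_pair, n_feats=150):
    _cfg, (a, b), truth = sim_pair
    feats = anchor_features(a, b, n_feats)
    return scale_features(a, feats), scale_features(b, feats), feats, truth


class TestFindAnchors:
    def test_self_alignment_identity_pairs(self, sim_pair):
        """Anchoring a dataset against its own copy pairs each cell with itself."""
        a, _b, feats, _ = prep_pair(sim_pair)
        # mutual 1-NN: the zero-distance copy is each cell's unique partner
        anchors = find_anchors(a, a.copy(), feats, dims=10, k_anchor=1)
        assert len(anchors.anchors) > 0
        identity = (anchors.anchors["cell_a"] == anchors.anchors["cell_b"]).mean()
        assert identity >= 0.99

    def test_anchor_type_agreement(self, sim_pair):
        """Across two simulated batches, anchors connect same-type cells."""
        a, b, feats, _ = prep_pair(sim_pair)
        anchors = find_anchors(a, b, feats, dims=10)
        ta = a.cells["true_type"].to_numpy()
        tb = b.cells["true_type"].to_numpy()
        agree = (ta[anchors.anchors["cell_a"]] == tb[anchors.anchors["cell_b"]]).mean()
        assert agree >= 0.90

    def test_pair_set_symmetric_on_identical_copies(self, sim_pair):
        """Swapping dataset roles reproduces the same unordered MNN pair set."""
        a, _b, feats, _ = prep_pair(sim_pair)
        fwd = find_anchors(a, a.copy(), feats, dims=10)
        rev = find_anchors(a.copy(), a, feats, dims=10)
        set_fwd = {tuple(sorted(p)) for p in
                   zip(fwd.anchors["cell_a"], fwd.anchors["cell_b"])}
        set_rev = {tuple(sorted(p)) for p in
                   zip(rev.anchors["cell_a"], rev.anchors["cell_b"])}
        assert set_fwd == set_rev

    def test_scores_in_unit_interval(self, sim_pair):
        a, b, feats, _ = prep_pair(sim_pair)
        anchors = find_anchors(a, b, feats, dims=10)
        s = anchors.anchors["score"]
        assert (s >= 0).all() and (s <= 1).all()

    def test_dims_exceeding_cells_error(self, make_atlas):
        import scipy.sparse as sp
        a = make_atlas(np.random.default_rng(0).poisson(2, (30, 5)))
        a.layers["normalized"] = sp.csr_matrix(a.counts, dtype=float)
        a = scale_features(a, a.genes.index)
        with pytest.raises(ValueError, match="cells"):
            find_anchors(a, a.copy(), list(a.genes.index), dims=10)

    def test_mnn_matches_bruteforce_oracle(self, sim_pair):
        """MNN pairs equal an exhaustive O(n^2) scan on a <= 50-cell instance."""
        a, b, feats, _ = prep_pair(sim_pair)
        a_small = a.subset(cell_mask=np.arange(40))
        b_small = b.subset(cell_mask=np.arange(45))
        anchors = find_anchors(a_small, b_small, feats, dims=10,
                               k_anchor=5, k_filter=1000)
        oracle = mutual_nearest_neighbors_bruteforce(
            anchors.emb_a, anchors.emb_b, k=5)
        impl = set(zip(anchors.anchors["cell_a"], anchors.anchors["cell_b"]))
        assert impl == oracle


class TestIntegrateExpression:
    def test_identical_datasets_unchanged(self, sim_pair):
        a, _b, feats, _ = prep_pair(sim_pair)
        # identity anchors carry zero difference vectors
        anchors = find_anchors(a, a.copy(), feats, dims=10, k_anchor=1)
        corrected, _ = integrate_expression(anchors, a, a.copy(), a.genes.index)
        orig = np.asarray(a.layers["normalized"].todense())
        np.testing.assert_allclose(corrected[:, a.n_cells:], orig, atol=1e-6)

    def test_planted_offset_removed(self, sim_pair):
        """A constant batch offset on one gene shrinks to <10% after correction."""
        a, b, feats, _ = prep_pair(sim_pair)
        delta = 2.0
        gene = feats[0]
        gi = b.genes.index.get_loc(gene)
        b_shift = b.copy()
        norm = b_shift.layers["normalized"].tolil()
        norm[gi, :] = norm[gi, :].toarray() + delta
        b_shift.layers["normalized"] = norm.tocsr()
        b_shift = scale_features(b_shift, feats)
        anchors = find_anchors(a, b_shift, feats, dims=10)
        corrected, _ = integrate_expression(anchors, a, b_shift, [gene])
        ref_mean = np.asarray(a.layers["normalized"][a.genes.index.get_loc(gene), :].todense()).mean()
        qry_mean = corrected[0, a.n_cells:].mean()
        assert abs(qry_mean - ref_mean) < 0.1 * delta

    def test_zero_scores_fall_back_to_uniform(self, sim_pair):
        a, b, feats, _ = prep_pair(sim_pair)
        anchors = find_anchors(a, b, feats, dims=10)
        anchors.anchors["score"] = 0.0
        corrected, _ = integrate_expression(anchors, a, b, feats[:5])
        assert np.isfinite(corrected).all()

    def test_empty_anchor_set_error(self, sim_pair):
        from atlascompare.integrate import AnchorSet
        a, b, feats, _ = prep_pair(sim_pair)
        empty = AnchorSet(anchors=pd.DataFrame(columns=["cell_a", "cell_b", "score"]),
                          features=feats, dims=10)
        with pytest.raises(ValueError, match="empty"):
            integrate_expression(empty, a, b, feats)


class TestClusterGraph:
    def test_planted_partition_recovery(self, sim_pair):
        """Well-separated simulated types are recovered with ARI >= 0.9."""
        a, b, feats, _ = prep_pair(sim_pair)
        anchors = find_anchors(a, b, feats, dims=10)
        corrected, _ = integrate_expression(anchors, a, b, feats)
        labels = cluster_graph(corrected, n_pcs=15, k_neighbors=15,
                               resolution=1.0, seed=0)
        truth = np.concatenate([a.cells["true_type"], b.cells["true_type"]])
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_low_resolution_single_cluster(self, null_atlas):
        """On a connected graph the resolution -> 0 limit is one community."""
        x = np.asarray(null_atlas.layers["normalized"].todense())
        labels = cluster_graph(x, n_pcs=10, k_neighbors=15,
                               resolution=1e-4, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_under_seed(self, sim_pair):
        a, _b, feats, _ = prep_pair(sim_pair)
        x = np.asarray(a.layers["scaled"])
        l1 = cluster_graph(x, n_pcs=10, k_neighbors=15, resolution=1.0, seed=3)
        l2 = cluster_graph(x, n_pcs=10, k_neighbors=15, resolution=1.0, seed=3)
        assert np.array_equal(l1, l2)

    def test_permutation_invariance_up_to_relabel(self, sim_pair):
        a, _b, feats, _ = prep_pair(sim_pair)
        x = np.asarray(a.layers["scaled"])
        perm = np.random.default_rng(0).permutation(x.shape[1])
        l1 = cluster_graph(x, n_pcs=10, k_neighbors=15, resolution=1.0, seed=0)
        l2 = cluster_graph(x[:, perm], n_pcs=10, k_neighbors=15,
                           resolution=1.0, seed=0)
        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)

    def test_k_exceeding_cells_error(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_graph(np.ones((5, 10)), n_pcs=2, k_neighbors=10,
                          resolution=1.0, seed=0)


class TestFindMarkers:
    def test_detection_fraction_filter(self, make_atlas):
        """A gene detected in 20% of cluster cells is excluded regardless of fold."""
        import scipy.sparse as sp
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :2] = 50   # gene present in 2/10 cluster-0 cells
        counts[1, :] = 5
        atlas = make_atlas(counts)
        atlas.layers["normalized"] = sp.csr_matrix(np.log1p(counts.astype(float)))
        labels = np.array([0] * 10 + [1] * 10)
        table = find_markers(atlas, labels, min_frac=0.25, min_log2fc=0.25)
        assert "g0" not in table.loc[table["cluster"] == 0, "gene"].tolist()

    def test_small_fold_change_excluded(self, make_atlas):
        import scipy.sparse as sp
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(3, 40))
        atlas = make_atlas(counts)
        norm = np.log1p(counts.astype(float))
        norm[0, :20] += 0.05  # log2FC well under 0.25
        atlas.layers["normalized"] = sp.csr_matrix(norm)
        labels = np.array([0] * 20 + [1] * 20)
        table = find_markers(atlas, labels)
        assert "g0" not in table["gene"].tolist()

    def test_planted_marker_significant(self, sim_pair):
        """A 4-fold fully detected planted marker reaches adjusted p < 0.05."""
        _cfg, (a, _b), truth = sim_pair
        labels = a.cells["true_type"].to_numpy()
        table = find_markers(a, labels)
        marker = truth.marker_genes["T01"][0]
        row = table[(table["cluster"] == "T01") & (table["gene"] == marker)]
        assert len(row) == 1
        assert row["p_adj"].iloc[0] < 0.05
        assert row["log2fc"].iloc[0] > 0.25

    def test_tiny_cluster_skipped_with_warning(self, make_atlas):
        import scipy.sparse as sp
        counts = np.random.default_rng(0).poisson(5, (4, 12))
        atlas = make_atlas(counts)
        atlas.layers["normalized"] = sp.csr_matrix(np.log1p(counts.astype(float)))
        labels = np.array([0] * 10 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            find_markers(atlas, labels)

    def test_merge_indistinct_clusters(self, sim_pair):
        """An artificial split of one true type is merged; distinct types are not."""
        from atlascompare.integrate import merge_indistinct_clusters
        _cfg, (a, _b), _ = sim_pair
        types = a.cells["true_type"].to_numpy()
        labels = types.astype(object).copy()
        t0 = np.flatnonzero(types == "T00")
        labels[t0[: len(t0) // 2]] = "T00_splitA"
        labels[t0[len(t0) // 2:]] = "T00_splitB"
        merged = merge_indistinct_clusters(a, labels)
        merged_t0 = np.unique(merged[t0])
        assert len(merged_t0) == 1  # the artificial split collapses
        assert len(np.unique(merged)) == len(np.unique(types))

    def test_shuffled_labels_type_i_control(self, null_atlas):
        """Label shuffles yield at most the nominal fraction of adjusted hits."""
        rng = np.random.default_rng(0)
        n = null_atlas.n_cells
        fracs = []
        for _ in range(20):
            labels = rng.permutation(np.array([0] * (n // 2) + [1] * (n - n // 2)))
            table = find_markers(null_atlas, labels, min_frac=0.0, min_log2fc=0.0)
            fracs.append((table["p_adj"] < 0.05).mean() if len(table) else 0.0)
        assert np.median(fracs) <= 0.05
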