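"""Binned-control signature scores and group comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlascompare.signatures import (module_score, per_gene_group_de,
                                     score_group_test)


def set_normalized(atlas, values):
    atlas.layers["normalized"] = sp.csr_matrix(np.asarray(values, dtype=float))
    return atlas


def brute_force_module_score(norm, gene_ids, gene_set, n_bins, n_ctrl, seed):
    """Independent dense recomputation: enumerate bins, replay the seeded draws,
    average with explicit per-cell loops."""
    norm = np.asarray(norm, dtype=float)
    means = {g: norm[i].mean() for i, g in enumerate(gene_ids)}
    order = sorted(gene_ids, key=lambda g: (means[g], list(gene_ids).index(g)))
    # stable mean-sorted order then equal-size bins
    order = [g for g, _ in sorted(((g, means[g]) for g in gene_ids),
                                  key=lambda t: t[1])]
    bin_of = {}
    for b, chunk in enumerate(np.array_split(np.asarray(order, dtype=object), n_bins)):
        for g in chunk:
            bin_of[g] = b
    rng = np.random.default_rng(seed)
    controls = []
    sig = set(gene_set)
    for g in gene_set:
        pool = [h for h in gene_ids if bin_of[h] == bin_of[g] and h not in sig]
        take = min(n_ctrl, len(pool))
        if take:
            controls.extend(rng.choice(np.asarray(pool, dtype=object),
                                       size=take, replace=False))
    idx = {g: i for i, g in enumerate(gene_ids)}
    n_cells = norm.shape[1]
    scores = np.zeros(n_cells)
    for c in range(n_cells):
        sig_mean = np.mean([norm[idx[g], c] for g in gene_set])
        ctrl_mean = np.mean([norm[idx[g], c] for g in controls])
        scores[c] = sig_mean - ctrl_mean
    return scores


class TestModuleScore:
    def test_matches_bruteforce_oracle(self, make_atlas):
        """30-gene, 5-cell hand-built matrix: implementation equals dense oracle."""
        rng = np.random.default_rng(4)
        norm = rng.gamma(2.0, 1.0, size=(30, 5))
        atlas = set_normalized(make_atlas(np.ones((30, 5), dtype=int)), norm)
        gene_set = ["g3", "g11", "g25"]
        sc = module_score(atlas, gene_set, n_bins=5, n_ctrl=4, seed=9)
        oracle = brute_force_module_score(
            norm, list(atlas.genes.index), gene_set, n_bins=5, n_ctrl=4, seed=9)
        np.testing.assert_allclose(sc.scores.to_numpy(), oracle, atol=1e-10)

    def test_null_construction_scores_zero(self, make_atlas):
        """Signature genes identical to every gene in their bin score exactly ~0."""
        rng = np.random.default_rng(0)
        blocks = []
        for b in range(4):
            row = rng.gamma(2.0, b + 1.0, size=(1, 8))
            blocks.append(np.tile(row, (10, 1)))  # 10 identical genes per bin
        norm = np.vstack(blocks)
        atlas = set_normalized(make_atlas(np.ones((40, 8), dtype=int)), norm)
        gene_set = ["g0", "g10", "g20", "g30"]  # one per bin
        for seed in range(20):
            sc = module_score(atlas, gene_set, n_bins=4, n_ctrl=5, seed=seed)
            assert np.abs(sc.scores.mean()) < 0.02

    def test_constant_shift_invariance(self, make_atlas):
        """Adding a constant to every gene cancels in the set-minus-control score."""
        rng = np.random.default_rng(1)
        norm = rng.gamma(2.0, 1.0, size=(50, 6))
        a1 = set_normalized(make_atlas(np.ones((50, 6), dtype=int)), norm)
        a2 = set_normalized(make_atlas(np.ones((50, 6), dtype=int)), norm + 3.7)
        gene_set = ["g5", "g17", "g33"]
        s1 = module_score(a1, gene_set, n_bins=5, n_ctrl=5, seed=2)
        s2 = module_score(a2, gene_set, n_bins=5, n_ctrl=5, seed=2)
        np.testing.assert_allclose(s1.scores, s2.scores, atol=1e-10)

    def test_planted_enrichment_detected(self, sim_pair):
        """The marker set of a planted type scores higher in that type's cells."""
        _cfg, (a, _b), truth = sim_pair
        gene_set = [g for g in truth.marker_genes["T00"] if g in a.genes.index]
        in_type = (a.cells["true_type"] == "T00").to_numpy()
        wins = 0
        for seed in range(40):
            sc = module_score(a, gene_set, seed=seed)
            if sc.scores[in_type].mean() > sc.scores[~in_type].mean():
                wins += 1
        assert wins >= 38  # >= 95% of seeds

    def test_absent_gene_dropped_with_warning(self, make_atlas):
        norm = np.random.default_rng(2).gamma(2.0, 1.0, size=(30, 4))
        atlas = set_normalized(make_atlas(np.ones((30, 4), dtype=int)), norm)
        with pytest.warns(UserWarning, match="absent"):
            sc = module_score(atlas, ["g1", "NOT_A_GENE"], n_bins=5, n_ctrl=3, seed=0)
        assert sc.gene_set == ["g1"]

    def test_all_absent_error(self, make_atlas):
        norm = np.ones((10, 3))
        atlas = set_normalized(make_atlas(np.ones((10, 3), dtype=int)), norm)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no signature gene"):
                module_score(atlas, ["NOPE"], seed=0)

    def test_seed_reproducibility(self, null_atlas):
        genes = list(null_atlas.genes.index[:10])
        s1 = module_score(null_atlas, genes, seed=5)
        s2 = module_score(null_atlas, genes, seed=5)
        pd.testing.assert_series_equal(s1.scores, s2.scores)


class TestScoreGroupTest:
    def test_exchangeable_groups_central_p(self, null_atlas):
        """Random splits of a null atlas give p-values centered near 0.5."""
        sc = module_score(null_atlas, list(null_atlas.genes.index[:25]), seed=0)
        rng = np.random.default_rng(0)
        n = null_atlas.n_cells
        ps = []
        for _ in range(200):
            group = np.zeros(n, dtype=bool)
            group[rng.choice(n, size=n // 2, replace=False)] = True
            ps.append(score_group_test(sc, group)["p"])
        assert 0.4 < np.median(ps) < 0.6

    def test_perfect_separation_small_p(self, make_atlas):
        """All group-A scores above all group-B scores at (20, 20): p < 1e-4."""
        norm = np.zeros((2, 40))
        norm[0, :20] = np.linspace(5, 6, 20)   # signature gene high in A
        norm[1, :] = 1.0
        atlas = set_normalized(make_atlas(np.ones((2, 40), dtype=int)), norm)
        from atlascompare.signatures import SignatureScore
        sc = SignatureScore(
            scores=pd.Series(norm[0] - norm[1], index=atlas.cells.index),
            gene_set=["g0"], control_genes=["g1"], n_bins=1, n_ctrl=1, seed=0)
        group = np.array([True] * 20 + [False] * 20)
        assert score_group_test(sc, group)["p"] < 1e-4

    def test_motor_neuron_like_enrichment(self, make_atlas):
        """A 4-fold 25-gene signature in a 300-cell group vs 5,000 others: p < 1e-4."""
        from atlascompare.qc import lognormalize
        from atlascompare.simgen import SimConfig, simulate_atlas
        cfg = SimConfig(
            cells_per_dataset=(5300, 300), n_genes=400, n_types=2,
            type_proportions=((300 / 5300, 5000 / 5300), (0.5, 0.5)),
            markers_per_type=25, marker_log2fc=2.0, seed=21,
        )
        atlases, truth = simulate_atlas(cfg)
        a = lognormalize(atlases[0])
        gene_set = truth.marker_genes["T00"]
        sc = module_score(a, gene_set, seed=0)
        group = (a.cells["true_type"] == "T00").to_numpy()
        res = score_group_test(sc, group)
        assert res["mean_in"] > res["mean_out"]
        assert res["p"] < 1e-4

    def test_empty_group_error(self, null_atlas):
        sc = module_score(null_atlas, list(null_atlas.genes.index[:5]), seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            score_group_test(sc, np.zeros(null_atlas.n_cells, dtype=bool))


class TestPerGeneGroupDe:
    def test_identical_groups_zero_log2fc(self, make_atlas):
        norm = np.tile(np.array([[1.0, 1.0, 1.0, 1.0]]), (3, 1))
        atlas = set_normalized(make_atlas(np.ones((3, 4), dtype=int)), norm)
        out = per_gene_group_de(atlas, [True, True, False, False], ["g0", "g1"])
        assert (out["log2fc"] == 0).all()

    def test_planted_sixteen_fold(self, make_atlas):
        """A 16-fold expm1-mean shift lands near log2((80+1)/(5+1)) = 3.75."""
        rng = np.random.default_rng(5)
        n_a, n_b = 300, 5000
        counts_a = rng.poisson(80.0, size=(1, n_a))
        counts_b = rng.poisson(5.0, size=(1, n_b))
        norm = np.log1p(np.hstack([counts_a, counts_b]).astype(float))
        atlas = set_normalized(
            make_atlas(np.ones((1, n_a + n_b), dtype=int)), norm)
        group = np.array([True] * n_a + [False] * n_b)
        out = per_gene_group_de(atlas, group, ["g0"])
        assert 3.5 <= out.loc["g0", "log2fc"] <= 4.5
        assert out.loc["g0", "p_adj"] < 0.05

    def test_absent_gene_flagged(self, make_atlas):
        norm = np.random.default_rng(6).gamma(2.0, 1.0, size=(5, 10))
        atlas = set_normalized(make_atlas(np.ones((5, 10), dtype=int)), norm)
        group = np.array([True] * 5 + [False] * 5)
        out = per_gene_group_de(atlas, group, ["g0", "MISSING", "g2"])
        assert out.loc["MISSING", "missing"]
        assert not out.loc["g0", "missing"]
        assert np.isfinite(out.loc["g0", "p"])

    def test_empty_list_error(self, null_atlas):
        with pytest.raises(ValueError, match="empty"):
            per_gene_group_de(null_atlas, np.ones(null_atlas.n_cells, bool), [])
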