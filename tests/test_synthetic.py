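"""Synthetic tissue generator: placement, Potts typing, NB count emission."""

import numpy as np
import pytest

import nichescope as ns
from nichescope.graph import build_contact_graph


def cross_type_edge_count(cellmap, graph, t1, t2):
    labels = cellmap["cell_type"].to_numpy()
    a = labels[graph.edges["a"].to_numpy()]
    b = labels[graph.edges["b"].to_numpy()]
    return int((((a == t1) & (b == t2)) | ((a == t2) & (b == t1))).sum())


class TestSimulateCellmap:
    def test_null_affinity_gives_no_pair_enrichment(self):
        cfg = ns.default_config(n_cells=1000, type_names=("A", "B"), n_genes=70, seed=5)
        cm, _ = ns.simulate_cellmap(cfg)
        g = build_contact_graph(cm)
        labels = cm["cell_type"].to_numpy()
        fA = (labels == "A").mean()
        observed = cross_type_edge_count(cm, g, "A", "B")
        expected = 2 * fA * (1 - fA) * len(g.edges)
        assert abs(np.log2(observed / expected)) < 0.2

    def test_planted_attraction_beats_permutation_null(self):
        wins = 0
        for seed in range(10):
            J = np.zeros((2, 2))
            J[0, 1] = J[1, 0] = 1.0
            cfg = ns.default_config(
                n_cells=1000, type_names=("A", "B"), n_genes=70, affinity=J, seed=seed
            )
            cm, _ = ns.simulate_cellmap(cfg)
            g = build_contact_graph(cm)
            observed = cross_type_edge_count(cm, g, "A", "B")
            rng = np.random.default_rng(seed + 1000)
            labels = cm["cell_type"].to_numpy()
            ea, eb = g.edges["a"].to_numpy(), g.edges["b"].to_numpy()
            null = np.empty(200)
            for i in range(200):
                perm = rng.permutation(labels)
                null[i] = ((perm[ea] != perm[eb])).sum()
            z = (observed - null.mean()) / null.std()
            wins += z > 3
        assert wins > 5

    def test_zone_assignment_is_radial(self):
        cfg = ns.default_config(n_cells=800, zone_radii=(200.0, 350.0), seed=2)
        cm, _ = ns.simulate_cellmap(cfg)
        r = np.hypot(cm["x"], cm["y"])
        assert (cm.loc[r < 200, "zone"] == "IZ").all()
        assert (cm.loc[(r >= 200) & (r < 350), "zone"] == "BZ").all()
        assert (cm.loc[r >= 350, "zone"] == "RZ").all()

    def test_minimum_separation_respected(self):
        cfg = ns.default_config(n_cells=500, seed=3)
        cm, _ = ns.simulate_cellmap(cfg)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cm[["x", "y"]].to_numpy()).query(cm[["x", "y"]].to_numpy(), k=2)
        assert d[:, 1].min() >= cfg.min_separation_um - 1e-9

    def test_same_seed_bit_identical(self):
        cfg1 = ns.default_config(n_cells=400, seed=9)
        cfg2 = ns.default_config(n_cells=400, seed=9)
        cm1, t1 = ns.simulate_cellmap(cfg1)
        cm2, t2 = ns.simulate_cellmap(cfg2)
        assert cm1.equals(cm2)
        c1 = ns.simulate_counts(cm1, t1, cfg1)
        c2 = ns.simulate_counts(cm2, t2, cfg2)
        assert (c1.X != c2.X).nnz == 0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            ns.default_config(type_names=("A", "B"), affinity=np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="probability"):
            ns.default_config(type_names=("A", "B"), type_proportions=np.array([0.7, 0.7]))
        with pytest.raises(ValueError, match="increasing"):
            ns.default_config(zone_radii=(300.0, 200.0))


class TestSimulateCounts:
    def test_counts_are_nonnegative_integers_and_overdispersed(self, small_tissue):
        counts = small_tissue["counts"]
        X = counts.to_dense()
        assert (X >= 0).all() and np.allclose(X, np.round(X))
        # overdispersion: variance exceeds mean for well-expressed genes
        mean = X.mean(axis=1)
        var = X.var(axis=1)
        high = mean > 2
        assert (var[high] > mean[high]).mean() > 0.9

    def test_empirical_mean_matches_configured_mean(self):
        cfg = ns.default_config(n_cells=1200, type_names=("A",), n_genes=40, seed=7)
        cfg.base_means[:, 30] = 5.0
        cm, truth = ns.simulate_cellmap(cfg)
        counts = ns.simulate_counts(cm, truth, cfg)
        x = counts.to_dense()[30]
        # gene 30 is outside every program block: NB(5, phi=0.2)
        se = np.sqrt((5 + 0.2 * 25) / x.size)
        assert abs(x.mean() - 5.0) < 3 * se

    def test_planted_fold_change_recovered(self):
        de_genes = list(range(30, 40))
        cfg = ns.default_config(
            n_cells=1000,
            type_names=("A",),
            n_genes=60,
            zone_radii=(150.0, 220.0),
            de_spec=(de_genes, 2.0, ("zone", "IZ")),
            seed=11,
        )
        cm, truth = ns.simulate_cellmap(cfg)
        counts = ns.simulate_counts(cm, truth, cfg)
        X = counts.to_dense()
        in_iz = (cm["zone"] == "IZ").to_numpy()
        assert in_iz.sum() > 300 and (~in_iz).sum() > 300
        ratio = X[np.ix_(de_genes, in_iz)].mean() / X[np.ix_(de_genes, ~in_iz)].mean()
        assert 1.8 < ratio < 2.2

    def test_zero_coupling_leaves_programs_independent(self):
        cfg = ns.default_config(n_cells=1000, type_names=("A", "B"), seed=13)
        cm, truth = ns.simulate_cellmap(cfg)
        g = build_contact_graph(cm)
        ns.simulate_counts(cm, truth, cfg, graph=g)
        act = truth.program_activities
        tidx = (cm["cell_type"] == "B").to_numpy().astype(int)
        nb = g.neighbor_lists()
        own, neigh = [], []
        for i in np.flatnonzero(tidx == 0):
            nbs = nb[i][tidx[nb[i]] == 1]
            if nbs.size:
                own.append(act[i, 0])
                neigh.append(act[nbs, 1].mean())
        r = np.corrcoef(own, neigh)[0, 1]
        assert abs(r) < 0.1

    def test_reference_mode_is_independent_draw(self, small_tissue):
        ref = ns.simulate_counts(
            small_tissue["cellmap"], small_tissue["truth"], small_tissue["config"], reference_mode=True
        )
        assert all(c.startswith("ref_") for c in ref.cells)
        assert ref.n_cells == len(small_tissue["cellmap"])
        assert (ref.X != small_tissue["counts"].X).nnz > 0
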