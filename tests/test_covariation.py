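"""Latent factors, neighbor design, ridge covariation, LR nomination."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import nichescope as ns
from nichescope.covariation import (
    CovariationResult,
    FactorModel,
    covariation_regression,
    factor_gene_correlation,
    fit_factors,
    load_lr_table,
    lr_candidates,
    match_factors,
    neighbor_factor_design,
)
from nichescope.data import lr_table_path
from nichescope.graph import ContactGraph

from conftest import make_counts


def single_type_cellmap(n, t="A"):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": np.arange(n, dtype=float),
            "y": np.zeros(n),
            "cell_type": [t] * n,
            "zone": ["none"] * n,
            "sample_id": ["s"] * n,
        }
    )


def chain_graph(ids):
    n = len(ids)
    a = np.arange(n - 1)
    b = a + 1
    adj = sp.csr_matrix((np.ones(2 * (n - 1), bool), (np.r_[a, b], np.r_[b, a])), shape=(n, n))
    return ContactGraph(
        cell_ids=list(ids),
        adjacency=adj,
        edges=pd.DataFrame({"a": a, "b": b, "distance_um": np.ones(n - 1)}),
    )


def model_from(cell_type, ids, activities, genes=2):
    activities = np.asarray(activities, dtype=float)
    k = activities.shape[1]
    loadings = np.eye(max(genes, k))[:genes, :k]
    return FactorModel(
        cell_type=cell_type,
        gene_names=[f"g{i}" for i in range(genes)],
        cell_ids=list(ids),
        loadings=loadings,
        activities=activities,
        k=k,
        reconstruction_error=0.0,
        seed=0,
    )


class TestFitFactors:
    def test_rank_one_matrix_reconstructed(self, rng):
        # the factorized matrix (log1p of the input) is exactly rank 1
        w = rng.uniform(0.5, 3.0, size=200)
        h = rng.random(30) + 0.1
        X = np.expm1(np.outer(h, w))  # genes x cells
        counts = make_counts(X, normalized=True)
        model = fit_factors(counts, single_type_cellmap(200), "A", k=1, seed=0)
        recon = model.activities @ model.loadings.T  # cells x genes
        if model.baseline_activity is not None:
            recon = recon + np.outer(model.baseline_activity, model.baseline_loading)
        target = np.log1p(X.T)
        err = np.linalg.norm(recon - target) / np.linalg.norm(target)
        assert err < 1e-3
        assert model.reconstruction_error < 1e-3

    def test_everything_non_negative(self, small_tissue):
        model = fit_factors(small_tissue["counts"], small_tissue["cellmap"], "A", k=3, seed=1)
        assert (model.loadings >= 0).all() and (model.activities >= 0).all()
        assert np.allclose(np.linalg.norm(model.loadings, axis=0), 1.0)

    def test_planted_programs_recovered_by_matching(self, small_tissue):
        truth, cm = small_tissue["truth"], small_tissue["cellmap"]
        for t, name in ((0, "A"), (1, "B")):
            model = fit_factors(small_tissue["counts"], cm, name, k=3, seed=0)
            gene_sets = [truth.program_genes[(t, p)] for p in range(3)]
            mapping = match_factors(model.loadings, gene_sets)
            for p, f in mapping.items():
                ind = np.zeros(model.loadings.shape[0])
                ind[gene_sets[p]] = 1
                ind /= np.linalg.norm(ind)
                assert ind @ model.loadings[:, f] > 0.8

    def test_k_too_large_errors(self, small_tissue):
        cm = small_tissue["cellmap"]
        two_a_cells = cm[cm["cell_type"] == "A"].head(2)
        with pytest.raises(ValueError, match="k="):
            fit_factors(small_tissue["counts"], two_a_cells, "A", k=3)


class TestNeighborFactorDesign:
    def test_single_neighbor_predictor_is_its_activity(self):
        g = chain_graph(["a0", "b0"])
        mA = model_from("A", ["a0"], [[1.0, 2.0]])
        mB = model_from("B", ["b0"], [[3.0, 4.0]])
        Y, X, ids, _ = neighbor_factor_design(g, mA, mB)
        assert ids == ["a0"]
        assert np.allclose(Y, [[1.0, 2.0]])
        assert np.allclose(X, [[3.0, 4.0]])

    def test_two_neighbors_averaged(self):
        # b0 - a0 - b1 chain: a0 contacts both B cells
        g = chain_graph(["b0", "a0", "b1"])
        mA = model_from("A", ["a0"], [[1.0, 1.0]])
        mB = model_from("B", ["b0", "b1"], [[1.0, 0.0], [0.0, 1.0]])
        _, X, _, _ = neighbor_factor_design(g, mA, mB)
        assert np.allclose(X, [[0.5, 0.5]])

    def test_no_contacts_errors_naming_pair(self):
        g = chain_graph(["a0", "a1"])
        mA = model_from("A", ["a0", "a1"], [[1.0, 0.0], [0.0, 1.0]])
        mB = model_from("B", [], np.zeros((0, 2)))
        with pytest.raises(ValueError, match=r"\(A, B\)"):
            neighbor_factor_design(g, mA, mB)


class TestCovariationRegression:
    def test_exact_ols_on_noise_free_line(self):
        x = np.linspace(1, 10, 50)[:, None]
        y = 2.0 * x
        res = covariation_regression(y, x, ridge_strength=0.0)
        assert res.beta[0, 0] == pytest.approx(2.0, abs=1e-9)
        assert res.p[0, 0] < 1e-12

    def test_huge_ridge_shrinks_everything(self, rng):
        X = rng.normal(size=(100, 3))
        Y = rng.normal(size=(100, 2))
        res = covariation_regression(Y, X, ridge_strength=1e9)
        assert np.abs(res.beta).max() < 1e-6

    def test_singular_design_needs_ridge(self, rng):
        x = rng.normal(size=(50, 1))
        X = np.hstack([x, x])  # perfectly collinear
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            covariation_regression(rng.normal(size=(50, 1)), X, ridge_strength=0.0)

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        reps = 300
        for _ in range(reps):
            X = rng.normal(size=(200, 1))
            y = rng.normal(size=(200, 1))
            rej += covariation_regression(y, X, ridge_strength=0.0).p[0, 0] < 0.05
        assert 0.02 < rej / reps < 0.08

    def test_too_few_rows_errors(self, rng):
        with pytest.raises(ValueError, match="n >"):
            covariation_regression(rng.normal(size=(3, 2)), rng.normal(size=(3, 3)))

    def test_grid_not_symmetric_between_roles(self, small_tissue):
        cm, g, counts = small_tissue["cellmap"], small_tissue["graph"], small_tissue["counts"]
        norm = ns.normalize_counts(counts)
        mA = fit_factors(norm, cm, "A", k=3, seed=0)
        mB = fit_factors(norm, cm, "B", k=3, seed=0)
        Yab, Xab, _, Zab = neighbor_factor_design(g, mA, mB)
        Yba, Xba, _, Zba = neighbor_factor_design(g, mB, mA)
        ab = covariation_regression(Yab, Xab, 1.0, nuisance=Zab)
        ba = covariation_regression(Yba, Xba, 1.0, nuisance=Zba)
        assert not np.allclose(ab.beta, ba.beta.T, atol=1e-3)


class TestFactorGeneCorrelation:
    def _model_and_counts(self, rng, n=300):
        act = rng.gamma(2, 1, size=(n, 1))
        genes = np.vstack(
            [
                np.expm1(act[:, 0]),  # monotone in activity -> rho = 1
                np.expm1(act[:, 0].max() - act[:, 0]),  # anti-monotone -> rho = -1
                rng.permutation(np.expm1(act[:, 0])),  # decoupled
                np.full(n, 2.0),  # constant
            ]
        )
        ids = [f"c{i}" for i in range(n)]
        counts = make_counts(genes, genes=["up", "down", "rand", "flat"], cells=ids, normalized=True)
        model = FactorModel(
            cell_type="A",
            gene_names=list(counts.genes),
            cell_ids=ids,
            loadings=np.ones((4, 1)) / 2.0,
            activities=act,
            k=1,
            reconstruction_error=0.0,
            seed=0,
        )
        return model, counts

    def test_monotone_genes_rank_at_extremes(self, rng):
        model, counts = self._model_and_counts(rng)
        rho = factor_gene_correlation(model, counts)
        ranked = rho["Fa0"].sort_values(ascending=False)
        assert ranked.index[0] == "up" and rho.loc["up", "Fa0"] == pytest.approx(1.0)
        assert ranked.index[-1] == "down" and rho.loc["down", "Fa0"] == pytest.approx(-1.0)
        assert abs(rho.loc["rand", "Fa0"]) < 0.15
        assert rho.loc["flat", "Fa0"] == 0.0
        assert "flat" in rho.attrs["constant_genes"]


class TestLRCandidates:
    @staticmethod
    def _cov(p_adj_01):
        p = np.full((2, 2), 0.9)
        p[0, 1] = p_adj_01
        return CovariationResult(
            central_type="A",
            niche_type="B",
            beta=np.full((2, 2), 0.5),
            t_stat=np.ones((2, 2)),
            p=p,
            p_adj=p,
            n_cells=100,
            ridge_strength=1.0,
        )

    @staticmethod
    def _corr(genes, hot, factor_count=2, hot_factor=0):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(-0.2, 0.2, size=(len(genes), factor_count)),
            index=genes,
            columns=[f"Fa{j}" for j in range(factor_count)],
        )
        for g in hot:
            df.loc[g, f"Fa{hot_factor}"] = 0.9
        return df

    def test_planted_pair_reported_with_factor_pair(self):
        table = pd.DataFrame({"ligand": ["Gas6"], "receptor": ["Axl"], "source": ["curated"]})
        corr_central = self._corr(["Axl", "x1", "x2"], ["Axl"], hot_factor=0)
        corr_niche = self._corr(["Gas6", "y1", "y2"], ["Gas6"], hot_factor=1)
        out = lr_candidates(self._cov(0.01), corr_central, corr_niche, table, top_n=2)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["ligand"], row["receptor"]) == ("Gas6", "Axl")
        assert (row["central_factor"], row["niche_factor"]) == (0, 1)
        assert row["p_adj"] == pytest.approx(0.01)

    def test_pair_absent_from_table_never_reported(self):
        table = pd.DataFrame({"ligand": ["Igf1"], "receptor": ["Igf1r"], "source": ["curated"]})
        corr_central = self._corr(["Axl"], ["Axl"])
        corr_niche = self._corr(["Gas6"], ["Gas6"], hot_factor=1)
        assert lr_candidates(self._cov(0.01), corr_central, corr_niche, table).empty

    def test_non_significant_grid_contributes_nothing(self):
        table = pd.DataFrame({"ligand": ["Gas6"], "receptor": ["Axl"], "source": ["curated"]})
        corr_central = self._corr(["Axl"], ["Axl"])
        corr_niche = self._corr(["Gas6"], ["Gas6"], hot_factor=1)
        assert lr_candidates(self._cov(0.5), corr_central, corr_niche, table).empty

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            lr_candidates(self._cov(0.01), self._corr(["a"], []), self._corr(["b"], []), pd.DataFrame())

    def test_bundled_table_loads_and_validates(self):
        table = load_lr_table(lr_table_path())
        assert {"ligand", "receptor", "source"} <= set(table.columns)
        assert not table.duplicated(["ligand", "receptor"]).any()
        assert len(table) >= 20
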