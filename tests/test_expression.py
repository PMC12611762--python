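"""Count-matrix utilities: filtering, normalization, NB DE test, BH, scores."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

import nichescope as ns
from nichescope.expression import bh_adjust, diffexpnb, filter_cells, gene_set_score, normalize_counts

from conftest import make_counts


def brute_force_bh(p):
    """Independent step-up oracle: adj_i = min over j with p_(j) >= p_(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestCountMatrix:
    def test_rejects_duplicate_names_and_negative_counts(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            make_counts(np.ones((2, 2)), genes=["g", "g"])
        with pytest.raises(ValueError, match="non-negative"):
            make_counts(np.array([[1, -1], [0, 2]]))

    def test_totals_are_column_sums(self, rng):
        X = rng.poisson(3, size=(10, 6))
        cm = make_counts(X)
        assert np.array_equal(cm.totals(), X.sum(axis=0))


class TestFilterCells:
    def test_strictly_greater_than_threshold(self):
        X = np.zeros((1, 3))
        X[0] = [900, 1000, 1001]
        kept = filter_cells(make_counts(X), min_umi=1000)
        assert kept.cells == ["c2"]

    def test_zero_threshold_is_identity_on_positive_totals(self, rng):
        cm = make_counts(rng.poisson(2, size=(5, 8)) + 1)
        kept = filter_cells(cm, min_umi=0)
        assert kept.cells == cm.cells

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            filter_cells(make_counts(np.zeros((3, 0))), min_umi=0)


class TestNormalize:
    def test_scales_to_minimum_total(self):
        X = np.array([[100.0, 100.0], [0.0, 100.0]])  # totals 100, 200
        norm = normalize_counts(make_counts(X))
        dense = norm.to_dense()
        assert np.allclose(dense[:, 1], [50.0, 50.0])
        assert np.allclose(dense.sum(axis=0), 100.0)

    def test_idempotent_and_zero_preserving(self, rng):
        X = rng.poisson(4, size=(30, 10)) + (rng.random((30, 10)) < 0.5)
        X[:, 0] += 1  # ensure positive totals
        once = normalize_counts(make_counts(X.astype(int)))
        twice = normalize_counts(once)
        assert np.allclose(once.to_dense(), twice.to_dense(), atol=1e-12)
        assert ((once.to_dense() == 0) == (X == 0)).all()

    def test_zero_total_cell_errors(self):
        X = np.array([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="filter"):
            normalize_counts(make_counts(X))

    def test_single_cell_unchanged(self):
        X = np.array([[3], [7]])
        norm = normalize_counts(make_counts(X))
        assert np.allclose(norm.to_dense(), X)


class TestBH:
    def test_equals_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(10_000):
            p = rng.random(rng.integers(1, 51))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_ties_collapse_to_common_value(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged_and_dominates_raw(self, rng):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        p = rng.random(40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        # order of evidence is preserved up to ties
        assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDiffExpNB:
    @staticmethod
    def _nb_matrix(rng, means, n_cells, a=0.1):
        r = 1.0 / a
        return rng.negative_binomial(r, r / (r + means[:, None]), size=(means.size, n_cells))

    def test_identical_groups_give_null_results(self):
        X = np.tile(np.arange(1, 11)[:, None], (1, 8))
        cm = make_counts(X)
        norm = normalize_counts(cm)
        res = diffexpnb(norm, norm.cells[:4], norm.cells[4:])
        assert np.allclose(res.table["log2_fc"], 0.0, atol=1e-9)
        assert (res.table["p"] > 0.99).all()

    def test_overlapping_groups_error(self):
        cm = normalize_counts(make_counts(np.ones((3, 4), dtype=int)))
        with pytest.raises(ValueError, match="overlap"):
            diffexpnb(cm, cm.cells[:3], cm.cells[2:])

    def test_zero_count_gene_skipped_and_reported(self, rng):
        X = rng.poisson(5, size=(4, 10)) + 1
        X[2] = 0
        res = diffexpnb(normalize_counts(make_counts(X)), [f"c{i}" for i in range(5)], [f"c{i}" for i in range(5, 10)])
        assert res.skipped_genes == ["g2"]
        assert "g2" not in set(res.table["gene"])

    def test_agrees_with_poisson_oracle_at_zero_dispersion(self, rng):
        # Poisson data: with a = 0 the test should match the exact
        # conditional binomial comparison of two Poisson rates within 0.02.
        # A filler gene equalizes per-cell totals so normalization is the
        # identity and raw sums are comparable.
        means = rng.uniform(2, 20, size=300)
        X = rng.poisson(means[:, None], size=(300, 60))
        filler = X.sum(axis=0).max() - X.sum(axis=0)
        X = np.vstack([X, filler])
        cm = make_counts(X)
        na = 30
        res = diffexpnb(normalize_counts(cm), cm.cells[:na], cm.cells[na:], alpha=0.0)
        table = res.table.set_index("gene")
        sum_a = X[:300, :na].sum(axis=1)
        tot = X[:300].sum(axis=1)
        oracle = np.minimum(
            2 * np.minimum(stats.binom.cdf(sum_a, tot, 0.5), stats.binom.sf(sum_a - 1, tot, 0.5)),
            1.0,
        )
        got = table.loc[[f"g{i}" for i in range(300)], "p"].to_numpy()
        assert np.abs(got - oracle).max() < 0.02


class TestGeneSetScore:
    def test_sums_normalized_expression(self):
        X = np.array([[3.0, 0.0], [4.0, 0.0], [9.0, 1.0]])
        cm = make_counts(X, normalized=True)
        cell, group = gene_set_score(cm, ["g0", "g1"], groups={"all": ["c0", "c1"]})
        assert cell["c0"] == pytest.approx(7.0)
        assert cell["c1"] == pytest.approx(0.0)
        assert group["all"] == pytest.approx(7.0)

    def test_log2_keeps_zero_at_zero(self):
        X = np.zeros((2, 1))
        cm = make_counts(X, normalized=True)
        cell, _ = gene_set_score(cm, ["g0", "g1"], log2=True)
        assert cell["c0"] == 0.0

    def test_linearity_in_expression(self, rng):
        X = rng.random((6, 5))
        c1, _ = gene_set_score(make_counts(X, normalized=True), ["g0", "g2"])
        c2, _ = gene_set_score(make_counts(2 * X, normalized=True), ["g0", "g2"])
        assert np.allclose(2 * c1, c2)

    def test_missing_genes_warn_and_empty_set_errors(self):
        cm = make_counts(np.ones((2, 2)), normalized=True)
        with pytest.warns(UserWarning, match="dropped"):
            gene_set_score(cm, ["g0", "nope"])
        with pytest.raises(ValueError):
            gene_set_score(cm, ["nope"])
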