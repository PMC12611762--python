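"""Expression-level statistics on UMI count matrices.

Implements the bulk/single-cell utilities of the pipeline: cell filtering by
total UMI count, depth normalization (scale every cell to the minimum total),
a negative-binomial background-model differential expression test,
Benjamini-Hochberg correction, and aggregated gene-set (e.g. cell-cycle
phase) scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "filter_cells",
    "normalize_counts",
    "diffexpnb",
    "bh_adjust",
    "gene_set_score",
]


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix with name metadata.

    Parameters
    ----------
    genes
        Unique gene names, one per row of ``X``.
    cells
        Unique cell identifiers, one per column of ``X``.
    X
        Sparse matrix of shape ``(n_genes, n_cells)``. Raw matrices hold
        non-negative integers; normalized matrices hold non-negative floats.
    normalized
        Whether :func:`normalize_counts` has been applied.
    """

    genes: list[str]
    cells: list[str]
    X: sp.csr_matrix
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for label, names in (("gene", self.genes), ("cell", self.cells)):
            seen: set[str] = set()
            for name in names:
                if name in seen:
                    raise ValueError(f"duplicate {label} name: {name!r}")
                seen.add(name)
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.normalized:
            data = self.X.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("raw counts must be integers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def totals(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def gene_index(self, names) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=int)

    def cell_index(self, ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        missing = [c for c in ids if c not in lookup]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return np.array([lookup[c] for c in ids], dtype=int)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            cells=[self.cells[i] for i in index],
            X=sp.csr_matrix(self.X[:, index]),
        )

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            genes=[self.genes[i] for i in index],
            X=sp.csr_matrix(self.X[index, :]),
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


@dataclass
class DEResult:
    """Per-gene differential expression summary between two cell groups."""

    table: pd.DataFrame  # gene, mean_a, mean_b, log2_fc, p, p_adj
    skipped_genes: list[str] = field(default_factory=list)
    dispersion_coef: float = float("nan")


def filter_cells(counts: CountMatrix, min_umi: int = 1000) -> CountMatrix:
    """Keep cells whose total UMI count is strictly greater than ``min_umi``.

    The strict inequality follows the convention of retaining cells with
    more than 1,000 UMIs.
    """
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    keep = np.flatnonzero(counts.totals() > min_umi)
    if keep.size == 0:
        raise ValueError(f"no cells exceed min_umi={min_umi}")
    return counts.subset_cells(keep)


def normalize_counts(counts: CountMatrix) -> CountMatrix:
    """Scale each cell to the minimum per-cell total.

    Each cell's counts are divided by its total and multiplied by the
    minimum total across cells, so every column sums to the same value and
    the sparsity pattern is unchanged. Idempotent.
    """
    totals = counts.totals()
    if np.any(totals <= 0):
        raise ValueError("zero-total cell present; run filter_cells first")
    scale = totals.min() / totals
    X = sp.csr_matrix(counts.X.astype(float).multiply(scale[np.newaxis, :]))
    return replace(counts, X=X, normalized=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def _background_dispersion(mean: np.ndarray, var: np.ndarray) -> float:
    """Fit a >= 0 in the variance model v(m) = m + a * m^2."""
    m2 = mean**2
    denom = float((m2**2).sum())
    if denom == 0:
        return 0.0
    a = float((m2 * (var - mean)).sum() / denom)
    return max(a, 0.0)


def diffexpnb(
    counts: CountMatrix,
    group_a,
    group_b,
    alpha: float | None = None,
) -> DEResult:
    """Negative-binomial background-model differential expression test.

    A quadratic mean-variance relation ``v(m) = m + a*m^2`` is fitted across
    genes on the pooled groups; per gene, the observed group-A sum is tested
    against its exact conditional null given the pooled total: if per-cell
    counts are NB with the background dispersion, the group sum conditioned
    on the total is beta-binomial with shape parameters proportional to the
    group sizes (two-sided: doubled smaller tail, capped at 1). As the
    fitted dispersion vanishes this reduces to the classic conditional
    binomial test of two Poisson rates. P-values are BH-corrected across
    tested genes.

    Parameters
    ----------
    counts
        Normalized count matrix (see :func:`normalize_counts`).
    group_a, group_b
        Disjoint iterables of cell ids.
    alpha
        Override for the fitted dispersion coefficient ``a`` (mainly for
        calibration studies).
    """
    ia = counts.cell_index(list(group_a))
    ib = counts.cell_index(list(group_b))
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be non-empty")
    if set(ia) & set(ib):
        raise ValueError("groups overlap")

    pooled = counts.X[:, np.concatenate([ia, ib])]
    mean = np.asarray(pooled.mean(axis=1)).ravel()
    # E[x^2] - mean^2 with (n-1) correction
    npool = pooled.shape[1]
    ex2 = np.asarray(pooled.multiply(pooled).mean(axis=1)).ravel()
    var = (ex2 - mean**2) * npool / max(npool - 1, 1)

    tested = mean > 0
    skipped = [g for g, t in zip(counts.genes, tested) if not t]

    a = _background_dispersion(mean[tested], var[tested]) if alpha is None else alpha
    mean_t = mean[tested]
    # dispersion floor keeps the NB size finite at low means
    v = np.maximum(mean_t + a * mean_t**2, 1.001 * mean_t)

    sum_a = np.asarray(counts.X[:, ia].sum(axis=1)).ravel()[tested]
    sum_b = np.asarray(counts.X[:, ib].sum(axis=1)).ravel()[tested]
    na, nb = ia.size, ib.size

    # per-cell NB size r = m^2 / (v - m); group sums are NB with sizes
    # na*r / nb*r, and sum_a | total is beta-binomial(total, na*r, nb*r)
    r = mean_t**2 / (v - mean_t)
    total = np.round(sum_a + sum_b)
    x = np.round(sum_a)
    lo = stats.betabinom.cdf(x, total, na * r, nb * r)
    hi = stats.betabinom.sf(x - 1, total, na * r, nb * r)
    pvals = np.minimum(2 * np.minimum(lo, hi), 1.0)

    mean_a = sum_a / na
    mean_b = sum_b / nb
    eps = 1e-9
    log2_fc = np.log2((mean_a + eps) / (mean_b + eps))

    table = pd.DataFrame(
        {
            "gene": [g for g, t in zip(counts.genes, tested) if t],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
        }
    )
    return DEResult(table=table, skipped_genes=skipped, dispersion_coef=a)


def gene_set_score(
    counts: CountMatrix,
    gene_set,
    groups: dict[str, list[str]] | None = None,
    log2: bool = False,
) -> tuple[pd.Series, pd.Series | None]:
    """Summed expression over a gene set per cell, optionally aggregated.

    Returns ``(cell_scores, group_scores)``; group scores are sums over the
    member cells. With ``log2=True`` scores are ``log2(x + 1)`` transformed
    (pseudo-count 1 keeps zero scores at zero).
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in set(counts.genes)]
    missing = [g for g in gene_set if g not in set(counts.genes)]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) not in matrix, dropped: {missing[:5]}")
    if not present:
        raise ValueError("no genes of the set are present in the matrix")
    rows = counts.gene_index(present)
    per_cell = np.asarray(counts.X[rows, :].sum(axis=0)).ravel()
    cell_scores = pd.Series(per_cell, index=pd.Index(counts.cells, name="cell_id"))

    group_scores = None
    if groups is not None:
        group_scores = pd.Series(
            {name: cell_scores.loc[list(ids)].sum() for name, ids in groups.items()}
        )
    if log2:
        cell_scores = np.log2(cell_scores + 1.0)
        if group_scores is not None:
            group_scores = np.log2(group_scores + 1.0)
    return cell_scores, group_scores
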