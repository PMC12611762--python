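"""Latent-factor covariation between colocalized cell types.

Per cell type, non-negative matrix factorization of the normalized,
log-transformed expression yields latent gene programs ("factors", Fa) whose
per-cell activities summarize intra-type expression variability. For a pair
of colocalized cell types, each central-type factor activity is ridge-
regressed on the mean factor activities of contacting niche-type cells;
significant coefficients (two-tailed t statistics, BH-corrected per grid)
indicate covariation of the underlying gene programs. Factor-correlating
genes intersected with a curated ligand-receptor table nominate candidate
signaling interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF

from .expression import CountMatrix, bh_adjust, normalize_counts
from .graph import ContactGraph

__all__ = [
    "FactorModel",
    "CovariationResult",
    "load_lr_table",
    "fit_factors",
    "neighbor_factor_design",
    "covariation_regression",
    "factor_gene_correlation",
    "match_factors",
    "lr_candidates",
]


@dataclass
class FactorModel:
    """Per-cell-type NMF factor model.

    ``loadings`` (genes x k) columns have unit L2 norm; the scale is pushed
    into ``activities`` (cells x k). Both are non-negative. The auxiliary
    baseline component (see :func:`fit_factors`) is kept separately:
    ``baseline_activity`` tracks each cell's depth/common-mode level and is
    used as a nuisance covariate in the covariation regression.
    """

    cell_type: str
    gene_names: list[str]
    cell_ids: list[str]
    loadings: np.ndarray
    activities: np.ndarray
    k: int
    reconstruction_error: float
    seed: int
    baseline_activity: np.ndarray | None = None
    baseline_loading: np.ndarray | None = None


@dataclass
class CovariationResult:
    """Ridge covariation grids for one ordered (central, niche) type pair."""

    central_type: str
    niche_type: str
    beta: np.ndarray  # (k_central, k_niche)
    t_stat: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    n_cells: int
    ridge_strength: float

    def to_frame(self) -> pd.DataFrame:
        kc, kn = self.beta.shape
        rows = [
            {
                "central_factor": i,
                "niche_factor": j,
                "beta": self.beta[i, j],
                "t": self.t_stat[i, j],
                "p": self.p[i, j],
                "p_adj": self.p_adj[i, j],
            }
            for i in range(kc)
            for j in range(kn)
        ]
        return pd.DataFrame(rows)


def fit_factors(
    counts: CountMatrix,
    cellmap: pd.DataFrame,
    cell_type: str,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 500,
) -> FactorModel:
    """NMF latent factors for one cell type.

    Counts are depth-normalized (if not already) and log1p-transformed, then
    factorized with NNDSVD-initialized coordinate-descent NMF restricted to
    the cells of ``cell_type``. One auxiliary component beyond ``k`` is
    fitted and set aside as the baseline (identified as the component with
    the flattest loading over genes); the remaining ``k`` factors describe
    the variable gene programs. Factor loadings are L2-normalized with the
    scale pushed to the activities.
    """
    ids = cellmap.loc[cellmap["cell_type"] == cell_type, "cell_id"].astype(str).tolist()
    if len(ids) == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    if k >= len(ids):
        raise ValueError(f"k={k} must be < number of {cell_type!r} cells ({len(ids)})")
    if k >= counts.n_genes:
        raise ValueError(f"k={k} must be < number of genes ({counts.n_genes})")
    if not counts.normalized:
        counts = normalize_counts(counts)
    sub = counts.subset_cells(counts.cell_index(ids))
    X = np.log1p(sub.to_dense().T)  # cells x genes

    # One extra component absorbs the dense baseline / depth common mode
    # shared by all genes; without it, every program factor would carry the
    # baseline and their activities would explain each other away.
    n_comp = k + 1 if k + 1 <= min(len(ids), counts.n_genes) else k
    model = NMF(n_components=n_comp, init="nndsvd", random_state=seed, max_iter=max_iter, tol=1e-5)
    W = model.fit_transform(X)  # cells x n_comp
    H = model.components_  # n_comp x genes

    baseline_act = None
    baseline_load = None
    if n_comp > k:
        # the baseline component has the flattest (highest-entropy) loading
        P = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
        entropy = -(P * np.log(np.maximum(P, 1e-12))).sum(axis=1)
        drop = int(np.argmax(entropy))
        keep = [f for f in range(n_comp) if f != drop]
        baseline_act = W[:, drop].copy()
        baseline_load = H[drop].copy()
        W, H = W[:, keep], H[keep]

    norms = np.linalg.norm(H, axis=1)
    norms[norms == 0] = 1.0
    loadings = (H / norms[:, None]).T  # genes x k, unit columns
    activities = W * norms[None, :]
    rel_err = model.reconstruction_err_ / max(np.linalg.norm(X), 1e-300)
    return FactorModel(
        cell_type=cell_type,
        gene_names=list(sub.genes),
        cell_ids=ids,
        loadings=loadings,
        activities=activities,
        k=k,
        reconstruction_error=float(rel_err),
        seed=seed,
        baseline_activity=baseline_act,
        baseline_loading=baseline_load,
    )


def neighbor_factor_design(
    graph: ContactGraph,
    central_model: FactorModel,
    niche_model: FactorModel,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray | None]:
    """Paired (response, predictor) activity matrices over contacting cells.

    For every central-type cell with at least one contacting niche-type
    cell: the response row is its own factor activities, the predictor row
    the unweighted mean of activities over its niche-type contacts. Returns
    ``(Y, X, cell_ids, nuisance)``; when both models carry a baseline
    component, ``nuisance`` holds the central cell's baseline activity and
    the mean niche baseline activity, to be regressed out as depth /
    common-mode covariates.
    """
    pos = {c: i for i, c in enumerate(graph.cell_ids)}
    niche_act = {
        pos[c]: i for i, c in enumerate(niche_model.cell_ids) if c in pos
    }
    neighbors = graph.neighbor_lists()
    has_base = (
        central_model.baseline_activity is not None
        and niche_model.baseline_activity is not None
    )

    Y_rows, X_rows, Z_rows, used = [], [], [], []
    for row_i, cid in enumerate(central_model.cell_ids):
        if cid not in pos:
            continue
        nb = [niche_act[j] for j in neighbors[pos[cid]] if j in niche_act]
        if nb:
            Y_rows.append(central_model.activities[row_i])
            X_rows.append(niche_model.activities[nb].mean(axis=0))
            if has_base:
                Z_rows.append(
                    [
                        central_model.baseline_activity[row_i],
                        niche_model.baseline_activity[nb].mean(),
                    ]
                )
            used.append(cid)
    if not used:
        raise ValueError(
            f"no {central_model.cell_type!r} cell has a contacting "
            f"{niche_model.cell_type!r} neighbor (pair "
            f"({central_model.cell_type}, {niche_model.cell_type}))"
        )
    nuisance = np.asarray(Z_rows) if has_base else None
    return np.asarray(Y_rows), np.asarray(X_rows), used, nuisance


def covariation_regression(
    Y: np.ndarray,
    X: np.ndarray,
    ridge_strength: float = 1.0,
    nuisance: np.ndarray | None = None,
    central_type: str = "central",
    niche_type: str = "niche",
) -> CovariationResult:
    """Ridge regression of each central factor on all niche factors.

    Predictors are z-scored for the fit and an intercept absorbed by
    centering; reported coefficients are back-transformed to the raw
    predictor scale. Optional ``nuisance`` columns (e.g. the baseline /
    depth activities from :func:`neighbor_factor_design`) enter the
    regression but not the reported grid or its BH family. Standard errors
    use the ridge sandwich form ``Var = s^2 A^-1 X'X A^-1`` with
    ``A = X'X + lambda I`` and residual degrees of freedom
    ``n - p_total - 1``; p-values are two-tailed t, BH adjusted across the
    k_central x k_niche grid.
    """
    if ridge_strength < 0:
        raise ValueError("ridge_strength must be >= 0")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k_niche = X.shape
    if nuisance is not None and len(nuisance):
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n:
            raise ValueError("nuisance must have the same number of rows as X")
        Xf = np.hstack([X, nuisance])
    else:
        Xf = X
    p = Xf.shape[1]
    if Y.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    if n <= p + 1:
        raise ValueError(f"need n > n_predictors + 1 cells (n={n}, predictors={p})")

    sd = Xf.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (Xf - Xf.mean(axis=0)) / sd_safe
    Yc = Y - Y.mean(axis=0)

    gram = Xs.T @ Xs
    if ridge_strength == 0 and np.linalg.matrix_rank(gram) < p:
        raise np.linalg.LinAlgError(
            "singular design with ridge_strength 0; use ridge_strength > 0"
        )
    Ainv = np.linalg.inv(gram + ridge_strength * np.eye(p))
    B = Ainv @ Xs.T @ Yc  # (p, k_central) standardized-scale coefficients

    df = n - p - 1
    resid = Yc - Xs @ B
    s2 = (resid**2).sum(axis=0) / df  # per response
    core = Ainv @ gram @ Ainv
    se = np.sqrt(np.outer(np.diag(core), s2))  # (p, k_central)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, np.where(B != 0, np.inf * np.sign(B), 0.0))
    pvals = 2 * stats.t.sf(np.abs(t), df)

    beta_raw = (B / sd_safe[:, None]).T  # (k_central, p)
    t = t.T
    pvals = pvals.T
    # report only the niche-factor columns; nuisance covariates are not tests
    beta_raw, t, pvals = beta_raw[:, :k_niche], t[:, :k_niche], pvals[:, :k_niche]
    return CovariationResult(
        central_type=central_type,
        niche_type=niche_type,
        beta=beta_raw,
        t_stat=t,
        p=pvals,
        p_adj=bh_adjust(pvals),
        n_cells=n,
        ridge_strength=ridge_strength,
    )


def match_factors(loadings: np.ndarray, gene_sets: list[np.ndarray]) -> dict[int, int]:
    """Best one-to-one assignment of gene sets to factors by loading cosine.

    ``gene_sets[p]`` holds the gene (row) indices of planted program ``p``;
    returns ``{program: factor}`` maximizing the total cosine similarity
    between each program's indicator vector and the factor loadings
    (Hungarian assignment). A convenience for recovery analyses on
    simulated tissues.
    """
    from scipy.optimize import linear_sum_assignment

    n_genes, k = loadings.shape
    sim = np.zeros((len(gene_sets), k))
    for p, genes in enumerate(gene_sets):
        ind = np.zeros(n_genes)
        ind[np.asarray(genes, dtype=int)] = 1.0
        ind /= np.linalg.norm(ind)
        sim[p] = ind @ loadings
    rows, cols = linear_sum_assignment(-sim)
    return dict(zip(rows.tolist(), cols.tolist()))


def factor_gene_correlation(model: FactorModel, counts: CountMatrix) -> pd.DataFrame:
    """Spearman correlation of each gene with each factor activity.

    Uses the normalized log expression of the model's cells. Returns a genes
    x factors DataFrame of correlations; constant genes get 0 and are
    flagged in ``df.attrs['constant_genes']``. Rank genes per factor by the
    column to obtain the positively / negatively correlated tails.
    """
    if not counts.normalized:
        counts = normalize_counts(counts)
    sub = counts.subset_cells(counts.cell_index(model.cell_ids))
    E = np.log1p(sub.to_dense())  # genes x cells

    ranks_g = stats.rankdata(E, axis=1)
    ranks_a = stats.rankdata(model.activities, axis=0).T  # k x cells

    def _corr(R1, R2):
        R1 = R1 - R1.mean(axis=1, keepdims=True)
        R2 = R2 - R2.mean(axis=1, keepdims=True)
        n1 = np.linalg.norm(R1, axis=1)
        n2 = np.linalg.norm(R2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            C = (R1 @ R2.T) / np.outer(n1, n2)
        return np.nan_to_num(C, nan=0.0)

    rho = _corr(ranks_g, ranks_a)  # genes x k
    df = pd.DataFrame(rho, index=sub.genes, columns=[f"Fa{j}" for j in range(model.k)])
    constant = [g for g, n in zip(sub.genes, np.ptp(E, axis=1)) if n == 0]
    df.attrs["constant_genes"] = constant
    return df


def load_lr_table(path) -> pd.DataFrame:
    """Read a ligand-receptor pair table (TSV: ligand, receptor[, source])."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if table.empty:
        raise ValueError("empty ligand-receptor table")
    cols = {c.lower(): c for c in table.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError("LR table must have 'ligand' and 'receptor' columns")
    table = table.rename(columns={cols["ligand"]: "ligand", cols["receptor"]: "receptor"})
    if "source" not in table.columns:
        table["source"] = "curated"
    if table[["ligand", "receptor"]].isna().any().any() or (
        table[["ligand", "receptor"]].astype(str) == ""
    ).any().any():
        raise ValueError("LR table contains empty gene names")
    if table.duplicated(["ligand", "receptor"]).any():
        raise ValueError("LR table contains duplicate pairs")
    return table


def lr_candidates(
    cov: CovariationResult,
    corr_central: pd.DataFrame,
    corr_niche: pd.DataFrame,
    lr_table: pd.DataFrame,
    adj_p_cut: float = 0.05,
    top_n: int = 200,
) -> pd.DataFrame:
    """Ligand-receptor candidates for significantly covarying factor pairs.

    For each factor pair with BH-adjusted p below ``adj_p_cut``, reports
    table pairs whose ligand is among the niche factor's ``top_n`` positively
    correlated genes and whose receptor is among the central factor's
    ``top_n``.
    """
    if lr_table is None or len(lr_table) == 0:
        raise ValueError("empty ligand-receptor table")
    rows = []
    kc, kn = cov.p_adj.shape
    for i in range(kc):
        for j in range(kn):
            if not cov.p_adj[i, j] < adj_p_cut:
                continue
            cc = corr_central.iloc[:, i]
            cn = corr_niche.iloc[:, j]
            receptors = set(cc[cc > 0].sort_values(ascending=False).head(top_n).index)
            ligands = set(cn[cn > 0].sort_values(ascending=False).head(top_n).index)
            for _, pair in lr_table.iterrows():
                if pair["ligand"] in ligands and pair["receptor"] in receptors:
                    rows.append(
                        {
                            "ligand": pair["ligand"],
                            "receptor": pair["receptor"],
                            "central_type": cov.central_type,
                            "central_factor": i,
                            "niche_type": cov.niche_type,
                            "niche_factor": j,
                            "beta": cov.beta[i, j],
                            "p_adj": cov.p_adj[i, j],
                            "ligand_rho": float(cn[pair["ligand"]]),
                            "receptor_rho": float(cc[pair["receptor"]]),
                            "source": pair.get("source", "curated"),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand",
            "receptor",
            "central_type",
            "central_factor",
            "niche_type",
            "niche_factor",
            "beta",
            "p_adj",
            "ligand_rho",
            "receptor_rho",
            "source",
        ],
    )
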