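"""Label transfer from a dissociated reference to spatial cells.

Spatial cells are clustered on their expression (kNN graph + Leiden at a
configurable resolution, the spatial guiding step), each cluster is anchored
to the reference cell type whose expression centroid it matches best by
Spearman correlation, and every cell inherits its cluster's type. Per-cell
confidence is the margin between the best and second-best centroid
correlation of the cell itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .expression import CountMatrix, normalize_counts

__all__ = ["LabelTransferResult", "transfer_labels"]


@dataclass
class LabelTransferResult:
    """Per-cell assignments from reference-guided clustering."""

    assignments: pd.DataFrame  # cell_id, cell_type, confidence, cluster
    cluster_types: pd.Series  # cluster id -> assigned type
    resolution: float
    n_unassigned: int


def _log_normalized(counts: CountMatrix) -> np.ndarray:
    if not counts.normalized:
        counts = normalize_counts(counts)
    return np.log1p(counts.to_dense())  # genes x cells


def transfer_labels(
    ref_counts: CountMatrix,
    ref_labels: pd.Series,
    spatial_counts: CountMatrix,
    resolution: float = 0.8,
    seed: int = 0,
    k_neighbors: int = 15,
) -> LabelTransferResult:
    """Assign reference cell-type labels to spatial cells.

    Parameters
    ----------
    ref_counts, ref_labels
        Dissociated reference matrix and per-cell type labels (indexed by
        the reference cell ids).
    spatial_counts
        Spatial (panel) count matrix; genes are intersected with the
        reference before normalization.
    resolution
        Leiden resolution of the spatial guiding clustering.

    Cells whose best centroid correlation is negative are flagged
    unassigned (type ``None``).
    """
    shared = [g for g in spatial_counts.genes if g in set(ref_counts.genes)]
    if len(shared) == 0:
        raise ValueError("no genes shared between reference and spatial matrices")
    if len(shared) < 50:
        warnings.warn(f"only {len(shared)} shared genes; label transfer may be unreliable")

    ref = ref_counts.subset_genes(ref_counts.gene_index(shared))
    spa = spatial_counts.subset_genes(spatial_counts.gene_index(shared))

    ref_labels = ref_labels.reindex(ref.cells)
    if ref_labels.isna().any():
        raise ValueError("reference labels missing for some reference cells")
    sizes = ref_labels.value_counts()
    small = sizes[sizes < 3].index.tolist()
    if small:
        warnings.warn(f"reference types with < 3 cells dropped: {small}")
        keep = np.flatnonzero(~ref_labels.isin(small).to_numpy())
        ref = ref.subset_cells(keep)
        ref_labels = ref_labels.iloc[keep]
    types = sorted(ref_labels.unique())
    if not types:
        raise ValueError("no usable reference types")

    E_ref = _log_normalized(ref)  # genes x cells
    E_spa = _log_normalized(spa)

    centroids = np.column_stack(
        [E_ref[:, (ref_labels == t).to_numpy()].mean(axis=1) for t in types]
    )  # genes x types

    # spatial guiding: Leiden communities on the expression kNN graph
    Xc = E_spa.T  # cells x genes
    k = min(k_neighbors, Xc.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
    _, idx = nn.kneighbors(Xc)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=Xc.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    clusters = np.asarray(part.membership)

    # per-cell Spearman correlation to each type centroid
    rc = stats.rankdata(centroids, axis=0)
    rs = stats.rankdata(E_spa, axis=0)
    rc = rc - rc.mean(axis=0)
    rs = rs - rs.mean(axis=0)
    denom = np.outer(np.linalg.norm(rs, axis=0), np.linalg.norm(rc, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_corr = np.nan_to_num((rs.T @ rc) / denom, nan=0.0)  # cells x types

    cluster_types = {}
    for c in np.unique(clusters):
        members = clusters == c
        centroid = E_spa[:, members].mean(axis=1)
        rr = stats.rankdata(centroid)
        rr = rr - rr.mean()
        nr = np.linalg.norm(rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.nan_to_num((rr @ rc) / (nr * np.linalg.norm(rc, axis=0)), nan=0.0)
        cluster_types[int(c)] = types[int(np.argmax(corr))]

    best = cell_corr.max(axis=1)
    if len(types) > 1:
        second = np.partition(cell_corr, -2, axis=1)[:, -2]
        confidence = np.clip(best - second, 0.0, 1.0)
    else:
        confidence = np.zeros(cell_corr.shape[0])  # degenerate: single type

    assigned = np.array([cluster_types[int(c)] for c in clusters], dtype=object)
    unassigned = best < 0
    assigned[unassigned] = None

    assignments = pd.DataFrame(
        {
            "cell_id": spa.cells,
            "cell_type": assigned,
            "confidence": confidence,
            "cluster": clusters,
        }
    )
    return LabelTransferResult(
        assignments=assignments,
        cluster_types=pd.Series(cluster_types),
        resolution=resolution,
        n_unassigned=int(unassigned.sum()),
    )
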