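"""Cell contact graph and niche composition features.

The niche of a cell is the cell itself plus its immediately contacting
neighbors (radius R = 0). Without segmentation masks, immediate contact is
approximated by a Delaunay triangulation of cell centroids with long edges
pruned; the per-cell niche composition is the neighbor cell-type frequency
vector, optionally normalized by global type frequencies (enrichment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError

__all__ = ["ContactGraph", "NicheComposition", "build_contact_graph", "niche_composition"]


@dataclass
class ContactGraph:
    """Undirected contact adjacency over cells.

    ``adjacency`` is a symmetric boolean CSR matrix with zero diagonal;
    ``edges`` lists each undirected edge once as (i, j, distance_um) with
    i < j, indices into ``cell_ids``.
    """

    cell_ids: list[str]
    adjacency: sp.csr_matrix
    edges: pd.DataFrame  # columns: a, b, distance_um
    method: str = "delaunay"
    prune_factor: float = 2.0

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def neighbor_lists(self) -> list[np.ndarray]:
        csr = self.adjacency.tocsr()
        return [csr.indices[csr.indptr[i] : csr.indptr[i + 1]] for i in range(self.n_cells)]

    def edge_table(self) -> pd.DataFrame:
        """Edge list with cell ids (cell_id_a, cell_id_b, distance_um)."""
        ids = np.asarray(self.cell_ids, dtype=object)
        return pd.DataFrame(
            {
                "cell_id_a": ids[self.edges["a"].to_numpy()],
                "cell_id_b": ids[self.edges["b"].to_numpy()],
                "distance_um": self.edges["distance_um"].to_numpy(),
            }
        )


@dataclass
class NicheComposition:
    """Cells x cell-types composition matrix of contact niches."""

    cell_ids: list[str]
    cell_types: list[str]  # type vocabulary (columns)
    matrix: np.ndarray
    mode: str  # "frequency" | "enrichment"
    global_frequencies: pd.Series
    isolated: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.cell_ids, name="cell_id"), columns=self.cell_types
        )


def _mutual_nearest_adjacency(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fallback for degenerate (e.g. collinear) point sets: mutual nearest."""
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    _, nn = tree.query(xy, k=2)
    nearest = nn[:, 1]
    pairs = {(min(i, j), max(i, j)) for i, j in enumerate(nearest) if nearest[j] == i}
    if not pairs:  # chain fallback: connect each cell to its nearest neighbor
        pairs = {(min(i, j), max(i, j)) for i, j in enumerate(nearest)}
    arr = np.array(sorted(pairs), dtype=int)
    return arr[:, 0], arr[:, 1]


def build_contact_graph(cellmap: pd.DataFrame, prune_factor: float = 2.0) -> ContactGraph:
    """Build the contact graph from cell centroids.

    Delaunay-triangulates the (x, y) centroids and removes edges longer than
    ``prune_factor`` times the median Delaunay edge length, a standard
    surrogate for membrane contact when segmentation masks are unavailable.

    Parameters
    ----------
    cellmap
        Cell table with columns ``cell_id``, ``x``, ``y``.
    prune_factor
        Multiple of the median edge length beyond which edges are cut.
    """
    if prune_factor <= 0:
        raise ValueError("prune_factor must be positive")
    n = len(cellmap)
    if n < 2:
        raise ValueError("need at least 2 cells to build a contact graph")
    xy = cellmap[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    cell_ids = cellmap["cell_id"].astype(str).tolist()

    uniq = np.unique(xy, axis=0)
    if uniq.shape[0] < xy.shape[0]:
        warnings.warn("duplicate coordinates detected; jittering by 1e-6 um")
        rng = np.random.default_rng(0)
        xy = xy + rng.normal(scale=1e-6, size=xy.shape)

    method = "delaunay"
    try:
        if n < 3:
            raise QhullError("too few points")
        tri = Delaunay(xy)
        simplices = tri.simplices
        pairs = np.vstack([simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        pairs = np.unique(pairs, axis=0)
        a, b = pairs[:, 0], pairs[:, 1]
    except QhullError:
        method = "mutual_nearest"
        a, b = _mutual_nearest_adjacency(xy)

    dist = np.linalg.norm(xy[a] - xy[b], axis=1)
    if method == "delaunay":
        keep = dist <= prune_factor * np.median(dist)
        a, b, dist = a[keep], b[keep], dist[keep]

    adjacency = sp.csr_matrix(
        (np.ones(2 * a.size, dtype=bool), (np.r_[a, b], np.r_[b, a])), shape=(n, n)
    )
    edges = pd.DataFrame({"a": a, "b": b, "distance_um": dist})
    return ContactGraph(
        cell_ids=cell_ids,
        adjacency=adjacency,
        edges=edges,
        method=method,
        prune_factor=prune_factor,
    )


def niche_composition(
    graph: ContactGraph, cellmap: pd.DataFrame, mode: str = "frequency"
) -> NicheComposition:
    """Per-cell niche composition over cell types.

    frequency mode: neighbor-type counts divided by degree (rows of
    non-isolated cells sum to 1). enrichment mode: frequency divided by the
    global type frequency over all mapped cells, i.e. the over-representation
    of each type in the niche relative to the tissue. The center cell is
    excluded from its own niche. Isolated cells get all-zero rows and are
    reported.
    """
    if mode not in ("frequency", "enrichment"):
        raise ValueError(f"unknown mode {mode!r}")
    cm = cellmap.set_index(cellmap["cell_id"].astype(str))
    missing = [c for c in graph.cell_ids if c not in cm.index]
    if missing:
        raise ValueError(f"cells missing type labels: {missing[:5]}")
    labels = cm.loc[graph.cell_ids, "cell_type"].astype(str).to_numpy()

    types = sorted(pd.unique(labels))
    type_idx = {t: j for j, t in enumerate(types)}
    onehot = np.zeros((graph.n_cells, len(types)))
    onehot[np.arange(graph.n_cells), [type_idx[t] for t in labels]] = 1.0

    counts = graph.adjacency.astype(float) @ onehot
    deg = graph.degrees().astype(float)
    isolated = [graph.cell_ids[i] for i in np.flatnonzero(deg == 0)]
    freq = np.divide(counts, deg[:, None], out=np.zeros_like(counts), where=deg[:, None] > 0)

    global_freq = pd.Series(onehot.mean(axis=0), index=types)
    matrix = freq
    if mode == "enrichment":
        gf = global_freq.to_numpy()
        zero = gf == 0
        if zero.any():
            warnings.warn(f"types with zero global frequency dropped: {list(np.array(types)[zero])}")
            matrix = freq[:, ~zero]
            types = [t for t, z in zip(types, zero) if not z]
            gf = gf[~zero]
            global_freq = global_freq[~(global_freq == 0)]
        matrix = matrix / gf[None, :]

    return NicheComposition(
        cell_ids=list(graph.cell_ids),
        cell_types=list(types),
        matrix=matrix,
        mode=mode,
        global_frequencies=global_freq,
        isolated=isolated,
    )
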