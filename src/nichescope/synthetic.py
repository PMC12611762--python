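"""Synthetic lesioned-tissue simulator with planted ground truth.

Emulates a multi-zone (IZ/BZ/RZ) tissue section: cells are placed in a disc
with a minimum-separation rule, assigned radial zone labels, and given cell
types by Gibbs sampling on the contact graph with a pairwise affinity matrix
J (log-odds units) planted on top of per-zone composition priors. UMI counts
are emitted per cell from a negative-binomial model whose means combine
per-type base profiles, multiplicative gene-program contributions with
Gamma-distributed activities, planted central<-niche program coupling, and
optional differential-expression fold changes. The planted structure is
returned as ground truth so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .expression import CountMatrix
from .graph import ContactGraph, build_contact_graph

__all__ = ["SimConfig", "SimTruth", "simulate_cellmap", "simulate_counts", "default_config"]

ZONES = ("IZ", "BZ", "RZ")


@dataclass
class SimConfig:
    """Parameters of the tissue and count simulator.

    Notes
    -----
    ``affinity`` is a symmetric matrix of pairwise log-odds: J[t, u] > 0
    makes type-t cells prefer type-u contacts (attraction), J < 0 repulsion.
    ``coupling`` entries are ``(central_type, central_program, niche_type,
    niche_program, strength)``: before count emission, a central cell's
    program activity is increased by ``strength`` times the mean activity of
    that program across its niche-type contacts.
    """

    n_cells: int = 3000
    type_names: tuple[str, ...] = ("A", "B", "C", "D", "E")
    type_proportions: Optional[np.ndarray] = None  # uniform if None
    affinity: Optional[np.ndarray] = None  # zero matrix if None
    zone_radii: tuple[float, float] = (200.0, 350.0)  # IZ, BZ outer radii (um)
    zone_composition: Optional[dict[str, np.ndarray]] = None  # per-zone priors
    tissue_radius_um: Optional[float] = None  # derived from density if None
    min_separation_um: float = 8.0
    gibbs_sweeps: int = 50
    n_genes: int = 160
    gene_names: Optional[tuple[str, ...]] = None
    base_means: Optional[np.ndarray] = None  # (n_types, n_genes), all > 0
    dispersion: Optional[np.ndarray] = None  # per-gene NB overdispersion phi
    n_programs_per_type: int = 3
    program_genes: Optional[dict[tuple[int, int], np.ndarray]] = None
    program_gene_mean: float = 1.5  # default base mean on a program's genes
    program_floor: float = 0.25  # activity-independent floor of the factor
    program_effect: float = 1.0  # gene mean factor = floor + effect * activity
    coupling: list[tuple[str, int, str, int, float]] = field(default_factory=list)
    de_spec: Optional[tuple[list, float, tuple[str, str]]] = None
    prune_factor: float = 2.0
    seed: int = 0

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def resolved(self) -> "SimConfig":
        """Fill derived defaults and validate; returns self."""
        nt, ng = self.n_types, self.n_genes
        if self.type_proportions is None:
            self.type_proportions = np.full(nt, 1.0 / nt)
        self.type_proportions = np.asarray(self.type_proportions, dtype=float)
        if self.affinity is None:
            self.affinity = np.zeros((nt, nt))
        self.affinity = np.asarray(self.affinity, dtype=float)
        if self.zone_composition is None:
            self.zone_composition = {z: self.type_proportions.copy() for z in ZONES}
        if self.tissue_radius_um is None:
            # ~1 cell per 225 um^2, a typical packing for cardiac sections
            self.tissue_radius_um = float(np.sqrt(self.n_cells * 225.0 / np.pi))
        if self.gene_names is None:
            self.gene_names = tuple(f"g{i:04d}" for i in range(ng))
        if self.program_genes is None:
            self.program_genes = _default_program_genes(
                nt, ng, self.n_programs_per_type, block_size=8, reserved=2 * nt
            )
        if self.base_means is None:
            means = _marker_base_means(nt, ng)
            # program genes are program-dominant modules of their own type
            for (t, _p), genes in self.program_genes.items():
                means[t, np.asarray(genes, dtype=int)] = self.program_gene_mean
            self.base_means = means
        self.base_means = np.asarray(self.base_means, dtype=float)
        if self.dispersion is None:
            self.dispersion = np.full(ng, 0.2)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self._validate()
        return self

    def _validate(self) -> None:
        nt, ng = self.n_types, self.n_genes
        if len(self.gene_names) != ng or len(set(self.gene_names)) != ng:
            raise ValueError("gene_names must be n_genes unique names")
        vecs = {"type_proportions": self.type_proportions}
        vecs.update({f"zone_composition[{z}]": v for z, v in self.zone_composition.items()})
        for name, v in vecs.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (nt,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector over {nt} types")
        if self.affinity.shape != (nt, nt) or not np.allclose(self.affinity, self.affinity.T):
            raise ValueError("affinity J must be a symmetric n_types x n_types matrix")
        if not (0 < self.zone_radii[0] < self.zone_radii[1]):
            raise ValueError("zone_radii must be strictly increasing and positive")
        if self.base_means.shape != (nt, ng) or np.any(self.base_means <= 0):
            raise ValueError("base_means must be (n_types, n_genes) with all entries > 0")
        if self.dispersion.shape != (ng,) or np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be per-gene and > 0")
        for ct, cp, ntp, np_, c in self.coupling:
            if ct not in self.type_names or ntp not in self.type_names:
                raise ValueError(f"coupling names unknown: {(ct, ntp)}")
            if not (0 <= cp < self.n_programs_per_type and 0 <= np_ < self.n_programs_per_type):
                raise ValueError("coupling program index out of range")
            if c < 0:
                raise ValueError("coupling strength must be >= 0")


def _marker_base_means(
    n_types: int, n_genes: int, baseline: float = 0.5, marker: float = 5.0, block: int = 2
) -> np.ndarray:
    """Base NB means: a flat baseline plus per-type marker gene blocks."""
    means = np.full((n_types, n_genes), baseline)
    for t in range(n_types):
        lo = t * block
        means[t, lo : min(lo + block, n_genes)] = marker
    return means


def _default_program_genes(
    n_types: int, n_genes: int, n_programs: int, block_size: int, reserved: int
) -> dict[tuple[int, int], np.ndarray]:
    """Disjoint per-(type, program) gene blocks, after the marker genes."""
    needed = reserved + n_types * n_programs * block_size
    if needed > n_genes:
        raise ValueError(
            f"n_genes={n_genes} too small for {n_types} types x {n_programs} "
            f"programs of {block_size} genes (+{reserved} markers); need {needed}"
        )
    out = {}
    pos = reserved
    for t in range(n_types):
        for p in range(n_programs):
            out[(t, p)] = np.arange(pos, pos + block_size)
            pos += block_size
    return out


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    affinity: np.ndarray
    zone_radii: tuple[float, float]
    coupling: list[tuple[str, int, str, int, float]]
    program_genes: dict[tuple[int, int], np.ndarray]
    de_genes: list = field(default_factory=list)
    de_fold: float = 1.0
    de_group: Optional[tuple[str, str]] = None
    program_activities: Optional[np.ndarray] = None  # (n_cells, n_programs) own-type
    cell_ids: Optional[list[str]] = None


def _poisson_disc(rng: np.random.Generator, n: int, radius: float, min_sep: float) -> np.ndarray:
    """Uniform points in a disc thinned to a minimum pairwise separation."""
    cell = min_sep / np.sqrt(2.0)
    grid: dict[tuple[int, int], int] = {}
    pts: list[tuple[float, float]] = []
    sep2 = min_sep**2
    attempts = 0
    max_attempts = 200 * n
    while len(pts) < n and attempts < max_attempts:
        m = min(4 * (n - len(pts)) + 64, 20000)
        r = radius * np.sqrt(rng.random(m))
        th = rng.random(m) * 2 * np.pi
        for x, y in zip(r * np.cos(th), r * np.sin(th)):
            attempts += 1
            gx, gy = int(x // cell), int(y // cell)
            ok = True
            for dx in range(-2, 3):
                for dy in range(-2, 3):
                    j = grid.get((gx + dx, gy + dy))
                    if j is not None:
                        px, py = pts[j]
                        if (px - x) ** 2 + (py - y) ** 2 < sep2:
                            ok = False
                            break
                if not ok:
                    break
            if ok:
                grid[(gx, gy)] = len(pts)
                pts.append((x, y))
                if len(pts) == n:
                    break
    if len(pts) < n:
        raise ValueError(
            f"could not place {n} cells with min separation {min_sep} um in a "
            f"disc of radius {radius:.0f} um; lower the density"
        )
    return np.asarray(pts)


def _greedy_coloring(neighbors: list[np.ndarray]) -> np.ndarray:
    colors = np.full(len(neighbors), -1, dtype=int)
    for i in range(len(neighbors)):
        used = set(colors[neighbors[i]])
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return colors


def simulate_cellmap(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Place cells, assign zones, and Gibbs-sample cell types.

    Type assignment runs chromatic Gibbs sweeps on the contact graph: the
    conditional log-probability of type t for a cell is
    ``log zone_composition[zone][t] + mean_neighbors J[t, type(neighbor)]``.
    The affinity term is degree-normalized (the mean over contacts, i.e. the
    inner product of J with the niche composition) so that the planted
    effect size is independent of local cell packing and moderate J values
    plant contact enrichment without driving the Potts model into an ordered
    phase that would wipe out rare types. Cells are updated color class by
    color class (a proper coloring of the contact graph), so each update
    conditions on fixed neighbors. The state after the configured number of
    sweeps is the sample (no burn-in discard).

    Returns the cell table (cell_id, x, y, cell_type, zone, sample_id) and
    the planted truth.
    """
    config.resolved()
    rng = np.random.default_rng([config.seed, 0])
    xy = _poisson_disc(rng, config.n_cells, config.tissue_radius_um, config.min_separation_um)

    rad = np.linalg.norm(xy, axis=1)
    zone = np.where(rad < config.zone_radii[0], "IZ", np.where(rad < config.zone_radii[1], "BZ", "RZ"))

    cell_ids = [f"cell_{i:05d}" for i in range(config.n_cells)]
    cellmap = pd.DataFrame(
        {"cell_id": cell_ids, "x": xy[:, 0], "y": xy[:, 1], "zone": zone, "sample_id": "sim"}
    )
    graph = build_contact_graph(cellmap.assign(cell_type="na"), prune_factor=config.prune_factor)
    neighbors = graph.neighbor_lists()
    colors = _greedy_coloring(neighbors)

    zones_arr = np.array([ZONES.index(z) for z in zone])
    log_comp = np.log(
        np.vstack([np.maximum(config.zone_composition[z], 1e-300) for z in ZONES])
    )  # (3, n_types)
    prior = log_comp[zones_arr]  # (n_cells, n_types)

    # init from the zone composition prior
    gumbel0 = rng.gumbel(size=(config.n_cells, config.n_types))
    types = np.argmax(prior + gumbel0, axis=1)

    adj = graph.adjacency.astype(float).tocsr()
    deg = np.maximum(graph.degrees().astype(float), 1.0)
    J = config.affinity
    color_classes = [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]
    onehot = np.zeros((config.n_cells, config.n_types))
    onehot[np.arange(config.n_cells), types] = 1.0
    for _ in range(config.gibbs_sweeps):
        for cls in color_classes:
            niche_frac = (adj[cls] @ onehot) / deg[cls, None]
            logits = prior[cls] + niche_frac @ J.T
            new = np.argmax(logits + rng.gumbel(size=logits.shape), axis=1)
            onehot[cls] = 0.0
            onehot[cls, new] = 1.0
            types[cls] = new

    cellmap["cell_type"] = np.asarray(config.type_names)[types]
    cellmap = cellmap[["cell_id", "x", "y", "cell_type", "zone", "sample_id"]]

    de_genes, de_fold, de_group = [], 1.0, None
    if config.de_spec is not None:
        de_genes, de_fold, de_group = config.de_spec
        de_genes = list(de_genes)
    truth = SimTruth(
        affinity=J.copy(),
        zone_radii=config.zone_radii,
        coupling=list(config.coupling),
        program_genes=dict(config.program_genes),
        de_genes=de_genes,
        de_fold=de_fold,
        de_group=de_group,
        cell_ids=cell_ids,
    )
    return cellmap, truth


def simulate_counts(
    cellmap: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    reference_mode: bool = False,
    graph: Optional[ContactGraph] = None,
) -> CountMatrix:
    """Emit NB-distributed UMI counts for the cells of ``cellmap``.

    Per cell, the gene mean is the type base mean times one multiplicative
    contribution ``program_floor + program_effect * activity`` per own-type
    program on that program's genes, times any planted DE fold. The small
    floor makes program genes program-dominant modules (their variance is
    driven by the activity, as for real co-regulated gene programs) so that
    factor analysis can identify them. Program activities are
    Gamma(2, 1) draws; planted coupling adds ``strength x mean niche-program
    activity over niche-type contacts`` to the central program activity
    before emission. ``reference_mode`` ignores positions and coupling and
    emits an independent dissociated dataset (cell ids prefixed ``ref_``)
    for label-transfer tests.
    """
    config.resolved()
    if len(cellmap) == 0:
        raise ValueError("empty cellmap")
    stream = 2 if reference_mode else 1
    rng = np.random.default_rng([config.seed, stream])

    type_idx = np.array([config.type_names.index(t) for t in cellmap["cell_type"]])
    n_cells, ng = len(cellmap), config.n_genes
    npr = config.n_programs_per_type

    activities = rng.gamma(shape=2.0, scale=1.0, size=(n_cells, npr))

    if not reference_mode and truth.coupling:
        if graph is None:
            graph = build_contact_graph(cellmap, prune_factor=config.prune_factor)
        neighbors = graph.neighbor_lists()
        base = activities.copy()
        for ct, cp, ntp, np_, c in truth.coupling:
            ci = config.type_names.index(ct)
            ni = config.type_names.index(ntp)
            for i in np.flatnonzero(type_idx == ci):
                nb = neighbors[i]
                nb = nb[type_idx[nb] == ni]
                if nb.size:
                    activities[i, cp] += c * base[nb, np_].mean()

    means = config.base_means[type_idx].copy()
    for (t, p), genes in config.program_genes.items():
        rows = np.flatnonzero(type_idx == t)
        if rows.size:
            factor = config.program_floor + config.program_effect * activities[rows, p]
            means[np.ix_(rows, genes)] *= factor[:, None]

    if truth.de_group is not None and not reference_mode:
        field_name, value = truth.de_group
        affected = np.flatnonzero(cellmap[field_name].to_numpy() == value)
        gidx = _resolve_genes(truth.de_genes, config)
        if affected.size:
            means[np.ix_(affected, gidx)] *= truth.de_fold

    phi = config.dispersion[None, :]
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + means))

    prefix = "ref_" if reference_mode else ""
    cells = [prefix + str(c) for c in cellmap["cell_id"]]
    if not reference_mode:
        truth.program_activities = activities
    return CountMatrix(genes=list(config.gene_names), cells=cells, X=sp.csr_matrix(counts.T))


def _resolve_genes(genes, config: SimConfig) -> np.ndarray:
    if len(genes) == 0:
        return np.array([], dtype=int)
    if all(isinstance(g, (int, np.integer)) for g in genes):
        return np.asarray(genes, dtype=int)
    lookup = {g: i for i, g in enumerate(config.gene_names)}
    return np.array([lookup[g] for g in genes], dtype=int)


def default_config(**overrides) -> SimConfig:
    """A resolved :class:`SimConfig` with any field overridden by keyword."""
    return SimConfig(**overrides).resolved()
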