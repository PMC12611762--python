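"""Seeded end-to-end recovery and calibration studies on synthetic tissue.

Each study simulates its own data with planted ground truth, runs the
corresponding pipeline stage, and reports recovery / calibration summaries.
They are the package's validation experiments: the analysis drivers, the
test suite and the acceptance script all call these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import synthetic
from .annotation import transfer_labels
from .covariation import (
    covariation_regression,
    fit_factors,
    match_factors,
    neighbor_factor_design,
)
from .expression import CountMatrix, diffexpnb, normalize_counts
from .graph import build_contact_graph, niche_composition
from .interaction import fit_interaction_map

__all__ = [
    "interaction_recovery_study",
    "covariation_recovery_study",
    "ridge_calibration_study",
    "de_calibration_study",
    "de_power_study",
    "label_transfer_study",
    "determinism_study",
]


def _interaction_tissue(seed: int, attraction: float, repulsion: float) -> pd.DataFrame:
    J = np.zeros((5, 5))
    J[0, 1] = J[1, 0] = attraction
    J[0, 2] = J[2, 0] = repulsion
    cfg = synthetic.default_config(n_cells=3000, affinity=J, seed=seed)
    cellmap, _ = synthetic.simulate_cellmap(cfg)
    return cellmap


def _fit_map(cellmap: pd.DataFrame, seed: int):
    graph = build_contact_graph(cellmap)
    comp = niche_composition(graph, cellmap, mode="enrichment")
    labels = pd.Series(
        cellmap["cell_type"].to_numpy(), index=cellmap["cell_id"].astype(str)
    )
    return fit_interaction_map(comp, labels, seed=seed)


def interaction_recovery_study(
    n_seeds: int = 20,
    seed: int = 0,
    attraction: float = 1.2,
    repulsion: float = -1.2,
    threshold: float = 0.14,
) -> dict:
    """Planted attraction/repulsion recovery on 3,000-cell 5-type tissues.

    Per seed, checks that the A<-B coefficient ranks among the top positive
    off-diagonal coefficients (top 2: the symmetric planted pair) and that
    A<-C is negative; on matched null tissues (J = 0), checks that no
    coefficient exceeds the network edge threshold.
    """
    recovered = negative = clean = 0
    for s in range(n_seeds):
        cellmap = _interaction_tissue(seed + s, attraction, repulsion)
        coef = _fit_map(cellmap, seed + s).coefficients
        off = coef.where(~np.eye(len(coef), dtype=bool).astype(bool))
        top2 = off.stack().nlargest(2).index
        recovered += ("A", "B") in list(top2)
        negative += coef.loc["A", "C"] < 0

        null_map = _interaction_tissue(seed + s + 10_000, 0.0, 0.0)
        null_coef = _fit_map(null_map, seed + s).coefficients
        clean += null_coef.to_numpy().max() <= threshold
    return {
        "recovery_rate": recovered / n_seeds,
        "repulsion_negative_rate": negative / n_seeds,
        "null_clean_rate": clean / n_seeds,
        "n_seeds": n_seeds,
    }


def covariation_recovery_study(
    n_seeds: int = 20,
    seed: int = 0,
    coupling_strength: float = 1.0,
    n_cells: int = 2000,
    k: int = 3,
) -> dict:
    """Planted factor-coupling recovery between two colocalized types.

    One coupling (A program 0 <- B program 1, strength c) is planted; per
    seed, factors are matched to the planted programs by loading cosine and
    the BH-adjusted covariation grid is evaluated: the coupled cell should
    be significant, the eight uncoupled cells should not.
    """
    hits = 0
    uncoupled_sig = 0
    uncoupled_total = 0
    for s in range(n_seeds):
        J = np.zeros((2, 2))
        J[0, 1] = J[1, 0] = 0.5
        cfg = synthetic.default_config(
            n_cells=n_cells,
            type_names=("A", "B"),
            affinity=J,
            coupling=[("A", 0, "B", 1, coupling_strength)],
            seed=seed + s,
        )
        cellmap, truth = synthetic.simulate_cellmap(cfg)
        graph = build_contact_graph(cellmap)
        counts = synthetic.simulate_counts(cellmap, truth, cfg, graph=graph)
        norm = normalize_counts(counts)
        m_a = fit_factors(norm, cellmap, "A", k=k, seed=seed + s)
        m_b = fit_factors(norm, cellmap, "B", k=k, seed=seed + s)
        map_a = match_factors(m_a.loadings, [truth.program_genes[(0, p)] for p in range(k)])
        map_b = match_factors(m_b.loadings, [truth.program_genes[(1, p)] for p in range(k)])
        Y, X, _, nuis = neighbor_factor_design(graph, m_a, m_b)
        cov = covariation_regression(Y, X, ridge_strength=1.0, nuisance=nuis)
        hits += cov.p_adj[map_a[0], map_b[1]] < 0.05
        for i in range(k):
            for j in range(k):
                if (i, j) != (0, 1):
                    uncoupled_sig += cov.p_adj[map_a[i], map_b[j]] < 0.05
                    uncoupled_total += 1
    return {
        "power": hits / n_seeds,
        "uncoupled_rate": uncoupled_sig / uncoupled_total,
        "n_seeds": n_seeds,
    }


def ridge_calibration_study(
    n: int = 200, reps: int = 1000, seed: int = 0, k: int = 3, ridge: float = 1.0
) -> dict:
    """Monte-Carlo type-I error of the ridge covariation test under the null."""
    rng = np.random.default_rng([seed, 77])
    rejected = total = 0
    for _ in range(reps):
        X = rng.normal(size=(n, k))
        Y = rng.normal(size=(n, k))
        res = covariation_regression(Y, X, ridge_strength=ridge)
        rejected += int((res.p < 0.05).sum())
        total += res.p.size
    return {"type1_error": rejected / total, "reps": reps, "n": n}


def _nb_counts(rng, means, n_cells, a):
    r = 1.0 / a
    return rng.negative_binomial(r, r / (r + means[:, None]), size=(means.size, n_cells))


def de_calibration_study(
    n_genes: int = 2000, n_per_group: int = 100, a: float = 0.1, seed: int = 0
) -> dict:
    """Type-I error of the NB background DE test on a null NB simulation."""
    rng = np.random.default_rng([seed, 88])
    means = rng.lognormal(np.log(5), 0.8, size=n_genes)
    X = _nb_counts(rng, means, 2 * n_per_group, a)
    cm = CountMatrix(
        [f"g{i}" for i in range(n_genes)], [f"c{i}" for i in range(2 * n_per_group)], sp.csr_matrix(X)
    )
    res = diffexpnb(
        normalize_counts(cm),
        [f"c{i}" for i in range(n_per_group)],
        [f"c{i}" for i in range(n_per_group, 2 * n_per_group)],
    )
    return {"type1_error": float((res.table["p"] < 0.05).mean()), "n_genes_tested": len(res.table)}


def de_power_study(
    n_background: int = 2000,
    n_de: int = 20,
    fold: float = 4.0,
    de_mean: float = 10.0,
    n_per_group: int = 100,
    a: float = 0.1,
    seed: int = 0,
) -> dict:
    """Power of the NB DE test for planted fold changes at BH 0.05."""
    rng = np.random.default_rng([seed, 99])
    means = rng.lognormal(np.log(5), 0.8, size=n_background)
    XA = _nb_counts(rng, means, n_per_group, a)
    XB = _nb_counts(rng, means, n_per_group, a)
    de_means = np.full(n_de, de_mean)
    DA = _nb_counts(rng, fold * de_means, n_per_group, a)
    DB = _nb_counts(rng, de_means, n_per_group, a)
    X = np.vstack([np.hstack([XA, XB]), np.hstack([DA, DB])])
    genes = [f"g{i}" for i in range(n_background)] + [f"de{i}" for i in range(n_de)]
    cells = [f"c{i}" for i in range(2 * n_per_group)]
    cm = CountMatrix(genes, cells, sp.csr_matrix(X))
    res = diffexpnb(
        normalize_counts(cm), cells[:n_per_group], cells[n_per_group:]
    )
    table = res.table.set_index("gene")
    de_rows = table.loc[[f"de{i}" for i in range(n_de)]]
    return {
        "power": float((de_rows["p_adj"] < 0.05).mean()),
        "median_log2_fc": float(de_rows["log2_fc"].median()),
        "n_de_genes": n_de,
    }


def label_transfer_study(n_cells: int = 1500, seed: int = 0, resolution: float = 0.8) -> dict:
    """Label-transfer accuracy from a matched dissociated reference."""
    cfg = synthetic.default_config(n_cells=n_cells, seed=seed)
    cellmap, truth = synthetic.simulate_cellmap(cfg)
    spatial = synthetic.simulate_counts(cellmap, truth, cfg)
    ref = synthetic.simulate_counts(cellmap, truth, cfg, reference_mode=True)
    ref_labels = pd.Series(cellmap["cell_type"].to_numpy(), index=ref.cells)
    res = transfer_labels(ref, ref_labels, spatial, resolution=resolution, seed=seed)
    acc = float(
        (res.assignments["cell_type"].to_numpy() == cellmap["cell_type"].to_numpy()).mean()
    )
    return {"accuracy": acc, "n_cells": n_cells, "n_unassigned": res.n_unassigned}


def determinism_study(tmp_dir, seed: int = 0) -> dict:
    """Two pipeline runs with the same (config, seed): manifest checksums match."""
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig.from_dict(
        {
            "stages": ["simulate", "transfer", "graph", "niche", "interact", "covary", "de", "score"],
            "seed": seed,
            "sim": {"n_cells": 1200, "type_names": ["A", "B", "C"], "coupling": [["A", 0, "B", 1, 1.0]]},
            "central_type": "A",
            "niche_type": "B",
        }
    )
    tmp_dir = Path(tmp_dir)
    m1 = run_pipeline(cfg, tmp_dir / "run1")
    m2 = run_pipeline(cfg, tmp_dir / "run2")
    return {
        "identical": m1["outputs"] == m2["outputs"],
        "n_outputs": len(m1["outputs"]),
    }
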