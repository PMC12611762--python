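"""Pipeline configuration and the staged end-to-end runner.

Ties the stages together: simulate -> transfer -> graph -> niche ->
interact -> covary -> de -> score, each toggleable, with every artifact
written as plain text and a manifest of SHA-256 checksums so that a rerun
with the same (config, seed) is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, covariation, graph, interaction, io, synthetic
from .data import g2m_genes, lr_table_path
from .expression import diffexpnb, filter_cells, gene_set_score, normalize_counts

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "transfer", "graph", "niche", "interact", "covary", "de", "score")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved parameters for a pipeline run.

    ``min_umi`` defaults to 0 here because the synthetic data emulates a
    targeted panel whose per-cell totals are far below whole-transcriptome
    depths; the library default of :func:`~nichescope.expression.filter_cells`
    remains 1,000 for dissociated data.
    """

    stages: tuple[str, ...] = ("simulate", "graph", "niche", "interact")
    seed: int = 0
    sim: dict = field(default_factory=dict)
    prune_factor: float = 2.0
    regularization: float = 1.0
    folds: int = 5
    threshold: float = 0.14
    k: int = 3
    ridge: float = 1.0
    min_umi: int = 0
    resolution: float = 0.8
    adj_p_cut: float = 0.05
    top_n: int = 200
    central_type: str | None = None
    niche_type: str | None = None
    de_group_field: str = "zone"
    de_group_a: str = "IZ"
    de_group_b: str = "BZ"
    score_gene_set: str | None = None  # path; built-in G2M list if None

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        cfg = cls(**payload)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the toggled stages and return the output manifest.

    The resolved configuration is written beside the outputs; each stage
    logs its parameters and row counts into the manifest. A failing stage
    aborts with a :class:`PipelineError` naming it; earlier outputs remain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": {}, "seed": config.seed}
    cfg_payload = asdict(config)
    cfg_payload["stages"] = list(config.stages)
    (out / "config.json").write_text(json.dumps(cfg_payload, indent=1, default=str))

    state: dict = {}
    requested = [s for s in STAGES if s in config.stages]
    deps = {
        "graph": ["simulate"],
        "niche": ["graph"],
        "interact": ["niche"],
        "covary": ["graph"],
        "transfer": ["simulate"],
        "de": ["simulate"],
        "score": ["simulate"],
    }
    for stage in requested:
        missing = [d for d in deps.get(stage, []) if d not in requested]
        if missing:
            raise PipelineError(f"stage '{stage}' requires stage(s) {missing} to be enabled")

    for stage in requested:
        try:
            info = _run_stage(stage, config, state, out)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = info

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_stage(stage: str, config: PipelineConfig, state: dict, out: Path) -> dict:
    if stage == "simulate":
        sim_cfg = synthetic.SimConfig(**{**config.sim, "seed": config.seed}).resolved()
        cellmap, truth = synthetic.simulate_cellmap(sim_cfg)
        counts = synthetic.simulate_counts(cellmap, truth, sim_cfg)
        state.update(cellmap=cellmap, truth=truth, counts=counts, sim_cfg=sim_cfg)
        io.write_cellmap(cellmap, out / "cellmap.csv")
        io.write_count_matrix(counts, out / "counts")
        io.write_truth(truth, out / "truth.json")
        return {"n_cells": len(cellmap), "n_genes": counts.n_genes}

    if stage == "transfer":
        sim_cfg, truth = state["sim_cfg"], state["truth"]
        ref_counts = synthetic.simulate_counts(
            state["cellmap"], truth, sim_cfg, reference_mode=True
        )
        ref_labels = pd.Series(
            state["cellmap"]["cell_type"].to_numpy(), index=ref_counts.cells
        )
        result = annotation.transfer_labels(
            ref_counts,
            ref_labels,
            state["counts"],
            resolution=config.resolution,
            seed=config.seed,
        )
        result.assignments.to_csv(out / "label_transfer.csv", index=False)
        state["transfer"] = result
        return {"n_unassigned": result.n_unassigned, "resolution": config.resolution}

    if stage == "graph":
        g = graph.build_contact_graph(state["cellmap"], prune_factor=config.prune_factor)
        state["graph"] = g
        g.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False)
        return {"n_edges": len(g.edges), "prune_factor": config.prune_factor}

    if stage == "niche":
        comp = graph.niche_composition(state["graph"], state["cellmap"], mode="enrichment")
        state["composition"] = comp
        comp.to_frame().to_csv(out / "niche_enrichment.csv")
        return {"n_isolated": len(comp.isolated), "mode": comp.mode}

    if stage == "interact":
        labels = pd.Series(
            state["cellmap"]["cell_type"].to_numpy(),
            index=state["cellmap"]["cell_id"].astype(str),
        )
        imap = interaction.fit_interaction_map(
            state["composition"],
            labels,
            regularization=config.regularization,
            folds=config.folds,
            seed=config.seed,
        )
        state["interaction"] = imap
        imap.coefficients.to_csv(out / "interaction_coefficients.csv")
        interaction.extract_network(imap, threshold=config.threshold).to_csv(
            out / "interaction_network.tsv", sep="\t", index=False
        )
        return {
            "overall_accuracy": imap.overall_accuracy,
            "threshold": config.threshold,
        }

    if stage == "covary":
        cellmap, counts = state["cellmap"], state["counts"]
        central = config.central_type or cellmap["cell_type"].iloc[0]
        niche_t = config.niche_type or next(
            t for t in cellmap["cell_type"].unique() if t != central
        )
        norm = normalize_counts(counts)
        m_central = covariation.fit_factors(norm, cellmap, central, k=config.k, seed=config.seed)
        m_niche = covariation.fit_factors(norm, cellmap, niche_t, k=config.k, seed=config.seed)
        Y, X, _, nuis = covariation.neighbor_factor_design(state["graph"], m_central, m_niche)
        cov = covariation.covariation_regression(
            Y,
            X,
            ridge_strength=config.ridge,
            nuisance=nuis,
            central_type=central,
            niche_type=niche_t,
        )
        cov.to_frame().to_csv(out / "covariation.csv", index=False)
        corr_c = covariation.factor_gene_correlation(m_central, norm)
        corr_n = covariation.factor_gene_correlation(m_niche, norm)
        cands = covariation.lr_candidates(
            cov,
            corr_c,
            corr_n,
            covariation.load_lr_table(lr_table_path()),
            adj_p_cut=config.adj_p_cut,
            top_n=config.top_n,
        )
        cands.to_csv(out / "lr_candidates.tsv", sep="\t", index=False)
        state["covariation"] = cov
        return {"central": central, "niche": niche_t, "n_cells": cov.n_cells}

    if stage == "de":
        cellmap, counts = state["cellmap"], state["counts"]
        if config.min_umi > 0:
            counts = filter_cells(counts, min_umi=config.min_umi)
        norm = normalize_counts(counts)
        kept = set(norm.cells)
        grp = cellmap[cellmap["cell_id"].astype(str).isin(kept)]
        ga = grp.loc[grp[config.de_group_field] == config.de_group_a, "cell_id"].astype(str)
        gb = grp.loc[grp[config.de_group_field] == config.de_group_b, "cell_id"].astype(str)
        result = diffexpnb(norm, ga, gb)
        result.table.to_csv(out / "de_results.csv", index=False)
        state["de"] = result
        return {
            "n_a": len(ga),
            "n_b": len(gb),
            "n_significant": int((result.table["p_adj"] < config.adj_p_cut).sum()),
        }

    if stage == "score":
        cellmap, counts = state["cellmap"], state["counts"]
        norm = normalize_counts(counts)
        if config.score_gene_set:
            genes = [
                line.strip()
                for line in Path(config.score_gene_set).read_text().splitlines()
                if line.strip()
            ]
        else:
            genes = g2m_genes()
        genes = [g for g in genes if g in set(norm.genes)] or list(norm.genes[:5])
        groups = {
            z: cellmap.loc[cellmap["zone"] == z, "cell_id"].astype(str).tolist()
            for z in cellmap["zone"].unique()
        }
        cell_scores, group_scores = gene_set_score(norm, genes, groups=groups, log2=True)
        cell_scores.rename("score").to_csv(out / "cell_scores.csv")
        group_scores.rename("score").to_csv(out / "group_scores.csv")
        return {"n_genes_scored": len(genes), "groups": sorted(groups)}

    raise PipelineError(f"unknown stage '{stage}'")
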