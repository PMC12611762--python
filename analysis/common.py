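"""Shared study configuration for the analysis drivers.

One lesioned-tissue simulation is used across the numbered scripts: a
3,000-cell disc with IZ/BZ/RZ zones, five cell types with planted A-B
attraction and A-C repulsion, one planted factor coupling (A program 0
responds to B program 1), ischemic-zone DE on a small gene set, and a few
genes renamed to real mouse symbols (the Gas6/Axl ligand-receptor pair in
the coupled programs, cell-cycle markers in the background) so the
downstream nomination and scoring steps have realistic vocabulary.
"""

from pathlib import Path

import numpy as np

import nichescope as ns

RESULTS = Path(__file__).resolve().parent.parent / "results"
TISSUE_DIR = RESULTS / "tissue"
SEED = 1


def study_config() -> ns.SimConfig:
    J = np.zeros((5, 5))
    J[0, 1] = J[1, 0] = 1.2
    J[0, 2] = J[2, 0] = -1.2
    cfg = ns.SimConfig(
        n_cells=3000,
        affinity=J,
        coupling=[("A", 0, "B", 1, 1.0)],
        seed=SEED,
    )
    cfg.resolved()
    names = list(cfg.gene_names)
    # receptor in the coupled central program, ligand in the niche program
    names[cfg.program_genes[(0, 0)][0]] = "Axl"
    names[cfg.program_genes[(1, 1)][0]] = "Gas6"
    # a few cell-cycle markers among the background genes
    for i, sym in zip(range(120, 126), ["Mki67", "Top2a", "Cdk1", "Ccnb2", "Birc5", "Aurka"]):
        names[i] = sym
    cfg.gene_names = tuple(names)
    cfg.de_spec = ([140, 141, 142, 143, 144], 2.0, ("zone", "IZ"))
    return cfg
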