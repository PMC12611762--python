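import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import nichescope as ns

warnings.filterwarnings("ignore", category=FutureWarning)


def make_counts(X, genes=None, cells=None, normalized=False):
    """Wrap a dense genes x cells array in a CountMatrix."""
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    cells = cells or [f"c{i}" for i in range(X.shape[1])]
    return ns.CountMatrix(genes=genes, cells=cells, X=sp.csr_matrix(X), normalized=normalized)


@pytest.fixture(scope="session")
def small_tissue():
    """A 1,200-cell three-type tissue with mild A-B attraction and one
    planted A<-B program coupling; shared across read-only tests."""
    J = np.zeros((3, 3))
    J[0, 1] = J[1, 0] = 0.5
    cfg = ns.default_config(
        n_cells=1200,
        type_names=("A", "B", "C"),
        affinity=J,
        coupling=[("A", 0, "B", 1, 1.0)],
        seed=42,
    )
    cellmap, truth = ns.simulate_cellmap(cfg)
    graph = ns.build_contact_graph(cellmap)
    counts = ns.simulate_counts(cellmap, truth, cfg, graph=graph)
    return {"config": cfg, "cellmap": cellmap, "truth": truth, "graph": graph, "counts": counts}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_cellmap():
    """Five cells in a row: types A, A, B, A, B."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(5)],
            "x": [0.0, 10.0, 20.0, 30.0, 40.0],
            "y": [0.0, 1.0, 0.0, 1.0, 0.0],
            "cell_type": ["A", "A", "B", "A", "B"],
            "zone": ["IZ"] * 5,
            "sample_id": ["s"] * 5,
        }
    )
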