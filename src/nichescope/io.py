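"""On-disk formats: Matrix Market count matrices, cell tables, truth JSON.

All files are plain text. Count matrices round-trip bit-exactly as integer
Matrix Market plus one-name-per-line ``genes.tsv`` / ``cells.tsv``;
coordinates are micrometer floats; files carry names, never indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .expression import CountMatrix
from .synthetic import SimTruth

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_cellmap",
    "write_cellmap",
    "write_truth",
    "read_truth",
]

CELLMAP_COLUMNS = ["cell_id", "x", "y", "cell_type", "zone", "sample_id"]


def write_count_matrix(counts: CountMatrix, directory) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = counts.X
    if not counts.normalized:
        X = X.astype(np.int64)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(X))
    (directory / "genes.tsv").write_text("\n".join(counts.genes) + "\n")
    (directory / "cells.tsv").write_text("\n".join(counts.cells) + "\n")


def _read_names(path: Path, label: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"{path} missing")
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    seen: set[str] = set()
    for i, name in enumerate(names, start=1):
        if name in seen:
            raise ValueError(f"duplicate {label} name {name!r} at {path}:{i}")
        seen.add(name)
    return names


def read_count_matrix(directory) -> CountMatrix:
    """Read a matrix written by :func:`write_count_matrix`."""
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(f"{mtx_path} missing")
    try:
        X = scipy.io.mmread(str(mtx_path))
    except ValueError as exc:
        raise ValueError(f"malformed matrix file {mtx_path}: {exc}") from exc
    X = sp.csr_matrix(X)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError(f"{mtx_path} describes an empty matrix")
    genes = _read_names(directory / "genes.tsv", "gene")
    cells = _read_names(directory / "cells.tsv", "cell")
    if X.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch at {mtx_path}: matrix {X.shape} vs "
            f"{len(genes)} genes / {len(cells)} cells"
        )
    normalized = not np.issubdtype(X.dtype, np.integer)
    return CountMatrix(genes=genes, cells=cells, X=X, normalized=normalized)


def write_cellmap(cellmap: pd.DataFrame, path) -> None:
    cellmap[CELLMAP_COLUMNS].to_csv(path, index=False)


def read_cellmap(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"cell_id": str})
    missing = [c for c in CELLMAP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell map {path} missing columns: {missing}")
    if table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"cell map {path} has duplicate cell_id {dup!r}")
    if not np.all(np.isfinite(table[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError(f"cell map {path} has non-finite coordinates")
    return table


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "affinity": np.asarray(truth.affinity).tolist(),
        "zone_radii": list(truth.zone_radii),
        "coupling": [list(c) for c in truth.coupling],
        "program_genes": {f"{t},{p}": np.asarray(g).tolist() for (t, p), g in truth.program_genes.items()},
        "de_genes": [int(g) if isinstance(g, (int, np.integer)) else g for g in truth.de_genes],
        "de_fold": truth.de_fold,
        "de_group": list(truth.de_group) if truth.de_group else None,
        "program_activities": None
        if truth.program_activities is None
        else np.asarray(truth.program_activities).tolist(),
        "cell_ids": truth.cell_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    return SimTruth(
        affinity=np.asarray(payload["affinity"]),
        zone_radii=tuple(payload["zone_radii"]),
        coupling=[tuple(c) for c in payload["coupling"]],
        program_genes={
            tuple(int(x) for x in key.split(",")): np.asarray(val, dtype=int)
            for key, val in payload["program_genes"].items()
        },
        de_genes=payload["de_genes"],
        de_fold=payload["de_fold"],
        de_group=tuple(payload["de_group"]) if payload["de_group"] else None,
        program_activities=None
        if payload["program_activities"] is None
        else np.asarray(payload["program_activities"]),
        cell_ids=payload["cell_ids"],
    )
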