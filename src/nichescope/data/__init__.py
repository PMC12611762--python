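"""Bundled text fixtures: cell-cycle phase gene lists and a curated
ligand-receptor pair table (mouse gene symbols). Editable one-gene-per-line
/ TSV files so panels with other vocabularies can swap them out."""

from importlib import resources
from pathlib import Path


def _read_list(name: str) -> list[str]:
    text = resources.files(__package__).joinpath(name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def s_genes() -> list[str]:
    """Canonical S-phase gene list (mouse symbols)."""
    return _read_list("s_genes.txt")


def g2m_genes() -> list[str]:
    """Canonical G2/M-phase gene list (mouse symbols)."""
    return _read_list("g2m_genes.txt")


def lr_table_path() -> Path:
    """Path to the bundled curated ligand-receptor pair table (TSV)."""
    return Path(str(resources.files(__package__).joinpath("lr_pairs.tsv")))
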