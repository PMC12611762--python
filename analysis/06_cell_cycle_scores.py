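"""Aggregated cell-cycle (G2/M) gene-set scores per lesion zone.

Sums normalized expression over the G2/M phase genes present in the panel
per cell, aggregates per zone, and reports the log2-transformed scores.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, TISSUE_DIR

import nichescope as ns
from nichescope import io
from nichescope.data import g2m_genes


def main() -> None:
    cellmap = io.read_cellmap(TISSUE_DIR / "cellmap.csv")
    counts = io.read_count_matrix(TISSUE_DIR / "counts")
    norm = ns.normalize_counts(counts)

    groups = {
        zone: cellmap.loc[cellmap["zone"] == zone, "cell_id"].tolist()
        for zone in sorted(cellmap["zone"].unique())
    }
    cell_scores, zone_scores = ns.gene_set_score(norm, g2m_genes(), groups=groups, log2=True)
    cell_scores.rename("g2m_score").to_csv(RESULTS / "g2m_cell_scores.csv")
    zone_scores.rename("g2m_score").to_csv(RESULTS / "g2m_zone_scores.csv")

    present = [g for g in g2m_genes() if g in set(norm.genes)]
    print(f"G2M score over {len(present)} panel genes: {present}")
    for zone, score in zone_scores.items():
        print(f"  {zone}: log2 aggregated score {score:.2f} ({len(groups[zone])} cells)")


if __name__ == "__main__":
    main()
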