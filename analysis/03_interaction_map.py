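"""Infer the cell-type interaction network from niche composition.

Builds the pruned-Delaunay contact graph, computes enrichment-mode niche
composition, fits the cross-validated multinomial classifier, and extracts
the directed network at the 0.14 edge-weight threshold. Reports whether the
planted A-B attraction and A-C repulsion are recovered.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, TISSUE_DIR

import pandas as pd

import nichescope as ns
from nichescope import io


def main() -> None:
    cellmap = io.read_cellmap(TISSUE_DIR / "cellmap.csv")
    graph = ns.build_contact_graph(cellmap)
    comp = ns.niche_composition(graph, cellmap, mode="enrichment")
    labels = pd.Series(cellmap["cell_type"].to_numpy(), index=cellmap["cell_id"])
    imap = ns.fit_interaction_map(comp, labels, seed=SEED)
    network = ns.extract_network(imap, threshold=0.14)

    imap.coefficients.to_csv(RESULTS / "interaction_coefficients.csv")
    network.to_csv(RESULTS / "interaction_network.tsv", sep="\t", index=False)
    graph.edge_table().to_csv(RESULTS / "contact_edges.tsv", sep="\t", index=False)

    print(f"contact graph: {len(graph.edges)} edges over {graph.n_cells} cells")
    print(f"classifier held-out accuracy: {imap.overall_accuracy:.3f}")
    print(f"coefficients: A<-B = {imap.coefficients.loc['A','B']:.3f} "
          f"(planted attraction), A<-C = {imap.coefficients.loc['A','C']:.3f} (planted repulsion)")
    print(f"network at threshold 0.14 ({len(network)} edges):")
    for _, e in network.iterrows():
        print(f"  {e['source']} -> {e['target']}  weight {e['weight']:.3f}")


if __name__ == "__main__":
    main()
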