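"""NB background-model differential expression between lesion zones.

Compares ischemic-zone (IZ) against border-zone (BZ) cells with the
negative-binomial background test and BH correction; the simulation planted
a 2-fold IZ increase on five genes, which should dominate the significant
set.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, TISSUE_DIR

import nichescope as ns
from nichescope import io


def main() -> None:
    cellmap = io.read_cellmap(TISSUE_DIR / "cellmap.csv")
    counts = io.read_count_matrix(TISSUE_DIR / "counts")
    truth = io.read_truth(TISSUE_DIR / "truth.json")
    norm = ns.normalize_counts(counts)

    group_a = cellmap.loc[cellmap["zone"] == "IZ", "cell_id"]
    group_b = cellmap.loc[cellmap["zone"] == "BZ", "cell_id"]
    res = ns.diffexpnb(norm, group_a, group_b)
    out = RESULTS / "de_iz_vs_bz.csv"
    res.table.to_csv(out, index=False)

    sig = res.table[res.table["p_adj"] < 0.05].sort_values("p_adj")
    planted = {counts.genes[i] for i in truth.de_genes}
    print(f"DE IZ (n={len(group_a)}) vs BZ (n={len(group_b)}): "
          f"{len(res.table)} genes tested, background dispersion a = {res.dispersion_coef:.3f}")
    print(f"significant at BH 0.05: {len(sig)} (planted: {sorted(planted)})")
    for _, r in sig.head(8).iterrows():
        tag = "planted" if r["gene"] in planted else ""
        print(f"  {r['gene']}: log2FC {r['log2_fc']:+.2f}, adjusted p {r['p_adj']:.2e} {tag}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
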