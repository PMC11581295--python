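#!/usr/bin/env python
"""Pairwise 2x2 decomposition of the reference lesion table, clustered.

Builds all 60 site-pair x subtype-pair Fisher tests from the simplified
4x5 reference table, bins the p-values into the five display colours,
clusters rows/columns (complete linkage, Euclidean), and writes the CSVs
and a rendered heatmap under results/.
"""

from pathlib import Path

from lungbm import exact, reference, vocab
from lungbm.pipeline import _render_heatmap

OUT = Path("results")


def main() -> None:
    table = reference.simplified_lesion_table()
    table.index = [vocab.SUBTYPE_ABBREV[s] for s in table.index]
    table.columns = [vocab.SITE_ABBREV[s] for s in table.columns]

    pairs = exact.all_pairs_2x2(table)
    rows, cols = exact.heatmap_order(pairs)
    ordered = pairs.loc[rows, cols]
    OUT.mkdir(parents=True, exist_ok=True)
    ordered.to_csv(OUT / "pairwise_pvalues.csv")
    ordered.map(exact.bin_pvalue).to_csv(OUT / "pairwise_pvalue_bins.csv")
    _render_heatmap(ordered, OUT / "pairwise_heatmap.png")

    n_sig = int((pairs.to_numpy() < 0.05).sum())
    print(f"{pairs.size} pairwise tests, {n_sig} with p < 0.05")
    cer = [c for c in pairs.columns if "CER" in c]
    print(f"site pairs involving the cerebellum: "
          f"{int((pairs[cer].to_numpy() < 0.05).sum())} of "
          f"{pairs[cer].size} significant")
    print(f"wrote {OUT/'pairwise_pvalues.csv'} and rendered heatmap")


if __name__ == "__main__":
    main()
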