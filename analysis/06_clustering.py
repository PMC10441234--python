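#!/usr/bin/env python
"""Hierarchical clustering of samples and top transcripts for heatmaps.

Reads quantities from results/quant/ and p-values from
results/differential/ (run 03 and 04 first). Clusters samples on both
the methylation and expression axes (Euclidean, complete linkage),
writes Newick dendrograms and z-scored top-50 heatmap matrices under
results/clustering/, and reports whether cutting each sample tree into
two clusters recovers the case/control split.
"""

import sys
from pathlib import Path

import pandas as pd

from meripchip.cluster import heatmap_matrix, hierarchical_cluster
from meripchip.quantify import read_quant_tsv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    quantdir = RESULTS / "quant"
    diffdir = RESULTS / "differential"
    if not (quantdir / "m6a_quantity.tsv").exists() or not (
        diffdir / "meth_diff.tsv"
    ).exists():
        sys.exit("missing inputs; run 03_quantify.py and 04_differential_calls.py")
    outdir = RESULTS / "clustering"
    outdir.mkdir(parents=True, exist_ok=True)

    for tag, quant_name, diff_name in (
        ("meth", "m6a_quantity.tsv", "meth_diff.tsv"),
        ("expr", "expression.tsv", "expr_diff.tsv"),
    ):
        values = read_quant_tsv(quantdir / quant_name)
        pvals = pd.read_csv(diffdir / diff_name, sep="\t", index_col=0)["p_value"]
        dendro = hierarchical_cluster(values, axis="samples")
        (outdir / f"dendrogram_{tag}_samples.nwk").write_text(
            dendro.to_newick() + "\n"
        )
        hm = heatmap_matrix(values, pvals, top_n=min(50, len(values)))
        hm.to_csv(outdir / f"heatmap_{tag}_top50.tsv", sep="\t")

        part = dendro.cut(2)
        chol = {part[s] for s in part if s.startswith("chol")}
        skin = {part[s] for s in part if s.startswith("skin")}
        split = len(chol) == 1 and len(skin) == 1 and chol != skin
        print(f"{tag}: sample leaf order {dendro.leaf_order}")
        print(f"{tag}: two-cluster cut separates the groups: {split}")


if __name__ == "__main__":
    main()
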