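#!/usr/bin/env python
"""Gene-set over-representation of the differential methylation calls.

Reads the methylation call table (run 04 first) and the toy GMT shipped
with the simulated experiment, tests the hyper- and hypomethylated gene
symbols against each set by the one-sided Fisher/hypergeometric test
over the on-array universe, and writes the enrichment tables (p, BH q,
-log10 p score) under results/enrichment/. The keratinization-like set
sits over the planted hypermethylation block, so it should surface for
the hyper query and not for the hypo query.
"""

import sys
from pathlib import Path

import pandas as pd

import meripchip as mc

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    diffdir = RESULTS / "differential"
    sim = RESULTS / "sim"
    if not (diffdir / "meth_diff.tsv").exists():
        sys.exit("no differential tables found; run 04_differential_calls.py")
    meth = pd.read_csv(diffdir / "meth_diff.tsv", sep="\t", index_col=0)
    design = mc.read_design(sim / "design.tsv")
    sets = mc.read_gmt(sim / "toy_sets.gmt")
    symbols = design.gene_symbol_of()
    universe = set(design.mrna["gene_symbol"])

    outdir = RESULTS / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)
    for label in ("hyper", "hypo"):
        query = set(symbols.reindex(
            meth.index[meth["direction"] == label]
        ).dropna())
        res = mc.fisher_enrichment(query, sets, universe)
        res.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t", index=False)
        print(f"{label} query ({len(query)} genes):")
        for _, row in res.iterrows():
            flag = "*" if row["significant"] else " "
            print(f"  {flag} {row['set_id']:<22} k={row['k']:>3}/{row['K']:<3} "
                  f"p={row['p_value']:.3g} score={row['score']:.2f}")


if __name__ == "__main__":
    main()
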