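#!/usr/bin/env python
"""Four-quadrant association of methylation and expression calls.

Reads the two call tables from results/differential/ (run 04 first),
cross-classifies every transcript, and writes the quadrant table, the
plot-ready table with the figure-legend colors, and the count summary
under results/association/. The hypomethylated-upregulated quadrant is
reported explicitly even when empty, as the study does.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from meripchip.association import (
    assign_quadrants,
    quadrant_counts,
    quadrant_plot_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    diffdir = RESULTS / "differential"
    if not (diffdir / "meth_diff.tsv").exists():
        sys.exit("no differential tables found; run 04_differential_calls.py")
    meth = pd.read_csv(diffdir / "meth_diff.tsv", sep="\t", index_col=0)
    expr = pd.read_csv(diffdir / "expr_diff.tsv", sep="\t", index_col=0)

    quad = assign_quadrants(meth, expr)
    counts = quadrant_counts(quad)
    outdir = RESULTS / "association"
    outdir.mkdir(parents=True, exist_ok=True)
    quad.to_csv(outdir / "quadrants.tsv", sep="\t")
    quadrant_plot_table(quad, meth, expr).to_csv(outdir / "quadrant_plot.tsv",
                                                 sep="\t")
    (outdir / "quadrant_summary.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True) + "\n"
    )
    print(json.dumps(counts, indent=2, sort_keys=True))
    if counts["hypo_up"] == 0:
        print("no hypomethylated-upregulated transcripts observed "
              "(the study reports the same empty quadrant)")


if __name__ == "__main__":
    main()
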