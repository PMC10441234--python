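#!/usr/bin/env python
"""MeRIP-qPCR validation of selected differentially methylated transcripts.

Reads the simulated Ct table written by 01 (the validation cohort: 10
cases vs 10 controls, 3 replicates, spike-in controls CTA850/CTA650),
converts Ct pairs to %input with the dilution correction, normalizes to
the per-sample positive control, compares groups per target with Welch's
test, and prints each comparison with its figure-style star code next to
the planted direction from the truth table. Writes tables under
results/qpcr/.
"""

import sys
from pathlib import Path

import pandas as pd

import meripchip as mc
from meripchip.qpcr import compare_all_targets, control_normalize
from meripchip.simulate import read_truth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = RESULTS / "sim"
    if not (sim / "qpcr.tsv").exists():
        sys.exit("no qPCR table found; run 01_simulate_experiment.py")
    table = pd.read_csv(sim / "qpcr.tsv", sep="\t")
    truth = read_truth(sim / "truth.tsv")

    norm = control_normalize(table, input_fraction=0.1)
    comps = compare_all_targets(norm)
    outdir = RESULTS / "qpcr"
    outdir.mkdir(parents=True, exist_ok=True)
    norm.to_csv(outdir / "qpcr_normalized.tsv", sep="\t", index=False)
    comps.to_csv(outdir / "qpcr_comparisons.tsv", sep="\t", index=False)

    print(f"{'target':<18} {'planted':<8} {'direction':<9} "
          f"{'p':>10}  stars")
    for _, row in comps.iterrows():
        planted = truth.loc[row["target_id"], "planted_meth"] \
            if row["target_id"] in truth.index else "?"
        print(f"{row['target_id']:<18} {planted:<8} {row['direction']:<9} "
              f"{row['p_value']:>10.3g}  {row['stars']}")


if __name__ == "__main__":
    main()
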