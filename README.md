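# meripchip

Analysis pipeline for **two-color m6A epitranscriptomic microarrays**,
modeled on a study of middle ear cholesteatoma (five lesion samples vs
five post-auricular skin controls). After MeRIP, the methylated (IP,
Cy5) and unmethylated (Sup, Cy3) fractions of each sample are hybridized
together on an array of 35,175 mRNA probes plus spike-in controls of
known methylation status. The package covers every computational stage
of that workflow, for analysts who have the probe-level intensity tables
(the raw study data are not deposited, so a synthetic generator with
planted truth stands in for them and makes every stage testable).

## What it computes

With spike-in normalized channels
`x̃(p,s) = log2 x(p,s) − mean_spike log2 x(spike,s)`:

- **m6A quantity** = normalized log2 IP intensity (methylation amount)
- **m6A percentage** = `100 · 2^ip / (2^ip + 2^sup)`
- **expression** = `log2(2^ip + 2^sup)`
- **differential calls**: FC = `2^(mean_chol − mean_skin)`, Welch t-test;
  hyper/up when FC ≥ 3 and p < 0.05, hypo/down when FC ≤ 1/3 and p < 0.05
- **four-quadrant association** of methylation × expression calls
- **Fisher's exact (hypergeometric) gene-set enrichment** with
  score = −log10 p over GMT files
- **hierarchical clustering** (Euclidean, complete linkage) for heatmaps
- **MeRIP-qPCR validation**: %input with dilution correction, spike-in
  control normalization, Welch group comparison with star codes
- **QC gates**: RNA purity (A260/A280 ∈ [1.8, 2.1], A260/A230 > 1.8),
  labeling yield/specific activity (two-color 825 ng & 8.0 pmol/µg;
  one-color 1.65 µg & 9.0 pmol/µg), MeRIP capture efficiency

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate a small experiment and run the full pipeline:

```
merip-chip simulate --outdir sim --n-transcripts 300 \
    --n-hyper 30 --n-hypo 30 --n-up 30 --n-down 30 --seed 7
merip-chip run --design sim/design.tsv --ip-raw sim/ip_raw.tsv \
    --sup-raw sim/sup_raw.tsv --gmt sim/toy_sets.gmt \
    --qpcr sim/qpcr.tsv --outdir run1
```

The run prints the JSON summary (abridged):

```
{"hyper_down": 0, "hyper_up": 32, "hypo_down": 30, "hypo_up": 0,
 "n_down": 30, "n_hyper": 60, "n_hypo": 60, "n_up": 32,
 "n_transcripts": 300, ...}
```

Reading it: the caller found 60 hypermethylated transcripts — the 30
planted hyper plus the 30 planted upregulated, because quadrupling a
transcript's copy number also quadruples its methylated copies — and 32
of the hyper calls are also expression-upregulated (`hyper_up`: the 30
planted up, plus two pushed over the expression threshold by noise).
No hypomethylated–upregulated transcripts exist
(`hypo_up: 0`), the same empty quadrant the source study reports. All
stage tables (normalized quantities, volcano/quadrant/heatmap tables,
enrichment, qPCR comparisons, Newick dendrograms) land in `run1/`.

The same stages are available as a narrative analysis at study scale
(35,175 probes) under `analysis/`; run the numbered scripts in order:

```
python analysis/01_simulate_experiment.py   # design, channels, truth
python analysis/02_qc_gates.py              # protocol QC gates
python analysis/03_quantify.py              # normalize + quantify
python analysis/04_differential_calls.py    # meth/expr calls, volcanoes
python analysis/05_quadrant_association.py  # four-quadrant intersection
python analysis/06_clustering.py            # dendrograms + heatmaps
python analysis/07_enrichment.py            # toy GMT over-representation
python analysis/08_qpcr_validation.py       # %input group comparisons
```

For instance, step 08 prints the validation-cohort comparisons
(10 vs 10 samples, 3 replicates), which recover every planted direction:

```
target             planted  direction          p  stars
ENST00000258499    hypo     lower       1.94e-07  ****
ENST00000266557    hyper    higher      6.01e-06  ****
ENST00000436547    hypo     lower       6.19e-07  ****
ENST00000536621    hypo     lower       7.29e-10  ****
ENST00000537824    hyper    higher      2.95e-05  ****
```

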