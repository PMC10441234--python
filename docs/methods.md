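# Methods

## Scope and data model

`meripchip` implements the analysis stages of a two-color m6A
epitranscriptomic microarray study of middle ear cholesteatoma (five
lesion samples vs five post-auricular skin controls) in which the
immunoprecipitated, Cy5-labeled methylated fraction (IP) and the
Cy3-labeled supernatant (Sup) of each sample are hybridized together on
an array carrying 35,175 mRNA probes plus exogenous spike-in controls of
known methylation status (methylated "positive" spikes, CTA850-like, and
unmethylated "negative" spikes, CTA650-like). The study deposited no raw
intensities, so the package ships a synthetic-data generator that
emulates the design with planted, recoverable effects; every downstream
stage is exercised and tested against that generator and against
independent oracles.

## Spike-in normalization and quantification

Each channel is normalized per sample against the average log2 spike-in
intensity of that channel:

    normalized(p, s) = log2 raw(p, s) − mean_spike log2 raw(spike, s)

Intensities are floored at 1.0 before the log (configurable), so zero
intensities map to log2(floor) = 0 rather than −∞. The protocol writes
this formula only for the IP/Cy5 channel against the IP spike-ins; we
normalize the supernatant analogously against the negative spikes, which
are recovered in the unmodified fraction. This is an interpretation, and
`spike_probes="all"` switches both channels to the pooled spike set. The
subtraction cancels any per-sample, channel-wide multiplicative factor
(dye incorporation, scanner gain); this scale invariance is property-
tested with random factors.

Three per-transcript quantities follow:

- **m6A quantity** — the normalized log2 IP intensity itself (the
  methylation *amount*).
- **m6A percentage** — the stated inputs are the two normalized
  channels, but no formula is printed; we use the only symmetric,
  scale-free combination mapping to [0, 100]:
  `100 · 2^ip / (2^ip + 2^sup)`. It depends only on ip − sup and is
  strictly increasing in it.
- **expression level** — the total of both channels in linear space,
  re-logged: `log2(2^ip + 2^sup)` (computed as `logaddexp2`), which
  bounds each addend from above.

Probe→transcript mapping is 1:1 in the default design; if several probes
share a transcript their linear intensities are averaged before
re-logging.

## Differential calling

Fold change is the ratio of geometric means, `2^(mean2 − mean1)`, with
group 2 = cholesteatoma and group 1 = skin; "hyper"/"up" means elevated
in cholesteatoma. Calls use the study's rule — FC ≥ 3 or ≤ 1/3
(inclusive) with p < 0.05 (strict) — applied to the m6A quantity for
methylation and the expression level for expression. The study never
names its test; the default is Welch's unequal-variance two-sample
t-test on log2 values (Student's by flag), since equal group variances
are not guaranteed. No multiple-testing correction is applied by default
(the study filters on raw p); Benjamini–Hochberg q-values can be
reported alongside. Degenerate rows with zero variance in both groups
get p = 1 when the means are equal and p = 0 otherwise; for volcano
tables −log10 p is capped at 320. The implementation is checked against
a hand-written Welch formula on 1,000 random instances (1e-10) and its
empirical size on exchangeable Gaussian nulls is verified to be
0.05 ± 0.01.

## Quadrant association

Transcripts significant on both axes fall into hyper_up, hyper_down,
hypo_up or hypo_down; all others are kept as `unassigned` so the
partition conserves the transcript universe (tested). Empty quadrants
are reported with count 0 — the study highlights the absence of
hypomethylated–upregulated mRNAs. Counts are verified against a
nested-loop set-intersection oracle.

## Clustering

Sample and transcript dendrograms use agglomerative clustering with
Euclidean distance and complete linkage (the study names neither; these
are the common heatmap defaults, both configurable) via scipy. Heatmap
blocks take the top-N transcripts by ascending p (stable tie-break on
input order), z-score each row with ddof = 1 (constant rows map to
zeros rather than NaN), and order rows/columns by dendrogram leaf order.
Exact distance ties are broken by scipy's internal merge order, which is
deterministic for a fixed input order; tie-free oracle instances are
used when comparing against a brute-force agglomerator. Dendrograms
serialize to Newick with height differences as branch lengths.

## Enrichment

Gene-set over-representation uses the one-sided hypergeometric tail
(equivalently Fisher's exact test for enrichment), with the score
−log10 p and significance at raw p < 0.05, as in the protocol; a
two-sided variant is available. The background universe defaults to the
gene symbols on the array, not the genome. Agreement with exact integer
enumeration is tested for every instance with N ≤ 25 at 1e-12. The
study's GO/KEGG term counts are annotation-database dependent and out of
scope; two toy GMT sets over the synthetic symbols keep the stage
testable hermetically.

## MeRIP-qPCR

Enrichment is percent of input with the standard dilution correction
(`adjusted input Ct = ct_input − log2(1/input_fraction)`;
`%input = 100 · 2^(adjusted − ct_ip)`), assuming perfect doubling per
cycle. The protocol states input normalization but not the reserved
fraction; the default 0.1 is an assumption the user must override with
the true value. Replicates (three per sample) are combined by the
arithmetic mean of %input — the quantity compared downstream — then each
target is divided by the same sample's positive-control %input, with the
negative control reported as the background floor and failing samples
flagged by the capture-efficiency gate and excluded from comparisons by
default. Groups (10 vs 10 in the validation cohort) are compared with a
two-sided Welch t-test and the figure-legend star code (** p<0.01,
*** p<0.001, **** p<0.0001, plus * for p<0.05).

## QC gates

RNA purity: A260/A280 within [1.8, 2.1] (inclusive) and A260/A230
strictly above 1.8. Labeling: specific activity = (pmol/µl dye)/(µg/µl
cRNA); hybridization stops when yield **and** specific activity are both
below the mode's thresholds (two-color: 825 ng, 8.0 pmol/µg; one-color:
1.65 µg, 9.0 pmol/µg), boundaries strict-below. The conjunction is the
protocol's literal wording; because common practice would stop on either
failure, `strict=True` switches to the disjunction. Spike-in capture:
positive/negative enrichment ratio ≥ 5.0 (inclusive); the protocol
states the check but no number, so the threshold is configurable. All
gates are monotone (property-tested).

## Synthetic-data generator

Per transcript t and sample s the baseline copy number is
`A0 = 2^(10 + e(t)·case(s) + z·σ)` with log2-additive Gaussian noise
(σ = 0.25 by default — the study reports no dispersion estimates, so
this is a documented stand-in) and e(t) the planted log2 expression
effect (down ratio 0.25; up transcripts get the reciprocal). The
baseline methylated fraction is f0 = 0.5. The planted methylation
effect m(t) (hyper ratio 4.0, hypo the reciprocal) multiplies the
*methylated copy number*: `IP = A0·f0·m`, `Sup = A0·(1−f0)`. This is
the same arithmetic as multiplying the odds of the methylated fraction
by m — the realized fraction is `f0·m/(1−f0+f0·m)`, always inside
(0, 1) — while the realized IP ratio equals m exactly in the noise-free
limit, which is what makes exact parameter recovery testable.

Two couplings follow from this model and are faithful to the assay:
methylation changes total abundance by `1−f0+f0·m` (a hyper transcript
with m = 4 gains 2.5× expression), and expression effects propagate into
the IP channel (an upregulated transcript has 4× more methylated
copies, so it is realized hypermethylated in *amount*). The truth table
therefore reports both the planted labels and the realized noise-free
ratios, with recovery labels derived from the realized ratios at the
calling thresholds. A consequence worth knowing: at f0 = 0.5 a
methylation-up/expression-down transcript (the study's small
hyper_down class, 38 mRNAs) cannot be realized, and the generator's
quadrant structure consists of hyper_up, hypo_down and the two empty
quadrants. Planted effect blocks are disjoint index ranges (hyper,
hypo, up, down, in manifest order), so the four counts must sum to at
most the transcript count.

Spike probes carry the spike level (log2 = 10) with the same noise in
their own channel and only background (1.0) in the other channel.
Optional per-sample per-channel scale factors (log2-uniform in a
configured range, default off) exercise the normalization's scale
invariance. All draws come from named SeedSequence substreams of one
integer seed; the abundance block is drawn in row-major order so
enlarging the design never perturbs existing rows.

The study-scale configuration plants counts equal to the study's
reported differential counts (4,620 hyper, 2,245 hypo, 4,891 up, 4,271
down of 35,175). Because of the expression→IP coupling, realized
methylation calls exceed the planted hyper/hypo blocks (up/down plants
are realized hyper_up/hypo_down); the generator makes no attempt to
reproduce the study's printed quadrant counts, which depend on real
stoichiometry the model does not carry.

The simulated qPCR cohort (10 vs 10 samples, 3 replicates) draws Ct
values from the ideal doubling model around each target's realized
fraction and abundance plus Gaussian cycle noise (SD = the array noise
SD by default), with control fractions 0.9 (CTA850) and 0.01 (CTA650).

What passing tests on this generator do *not* show: robustness to
probe-level cross-hybridization, spatial artifacts, background
structure, non-log-normal noise, or annotation ambiguity — none of
which the generator models.

## Problem sizes and numerics

Test and acceptance runs use 200–1,000-transcript designs for
Monte-Carlo work (20 seeds for sensitivity/null-rate and clustering
checks) and the full 35,175-probe design for the study-scale pass —
sizes chosen so the whole suite completes in well under a minute while
keeping every estimate's Monte-Carlo error far from its acceptance
margin. Key tolerances: noise-free recovery 1e-9; Welch-vs-formula
1e-10; hypergeometric-vs-enumeration 1e-12; scale invariance 1e-8 on
log2 values.

## Design choices and limitations

- The analysis-facing CLI (`merip-chip`) emits plot-ready tables,
  Newick trees and JSON summaries only; no figure rendering.
- Fold change for methylation is computed on m6A quantity, not m6A
  percentage, consistent with the protocol's definition of the
  methylation amount; configurable at the library level by passing the
  percentage matrix instead.
- The validation table's extreme fold changes (0.001–0.002) suggest the
  vendor pipeline may apply scaling beyond the printed formulas; the
  package implements exactly the printed arithmetic.
- Moderated/empirical-Bayes tests, paired designs, background
  subtraction, loess/quantile normalization and GO-DAG-aware enrichment
  are deliberately out of scope.
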