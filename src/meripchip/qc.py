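"""Numeric quality-control gates for the array workflow.

Three checkpoints precede hybridization and analysis:

1. RNA purity from NanoDrop absorbance ratios (A260/A280 within
   [1.8, 2.1]; A260/A230 strictly above 1.8).
2. Labeling yield and specific activity (pmol dye per ug cRNA). The
   protocol stops hybridization when yield AND specific activity both
   fall below the mode-specific thresholds (two-color: 825 ng and
   8.0 pmol/ug; one-color: 1.65 ug and 9.0 pmol/ug). The conjunction is
   implemented literally; ``strict=True`` switches to the more
   conservative disjunction (stop if either is low).
3. MeRIP capture efficiency from the spike-in qPCR: the positive
   (methylated) spike must be enriched over the negative spike by at
   least ``min_ratio`` (default 5.0; the protocol states no number).

All gates are monotone: improving a metric never flips pass into fail.
"""

from __future__ import annotations

import dataclasses

from .errors import ValidationError

A260_A280_LO = 1.8
A260_A280_HI = 2.1
A260_A230_MIN = 1.8

TWO_COLOR_YIELD_NG = 825.0
TWO_COLOR_SA = 8.0
ONE_COLOR_YIELD_NG = 1650.0
ONE_COLOR_SA = 9.0

SPIKE_RATIO_DEFAULT = 5.0
_EPS = 1e-12


@dataclasses.dataclass
class GateResult:
    """Outcome of one QC gate with human-readable reasons and metrics."""

    name: str
    passed: bool
    reasons: list[str]
    metrics: dict[str, float]

    def summary_lines(self) -> list[str]:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"[{status}] {self.name}"]
        for k, v in self.metrics.items():
            lines.append(f"    {k} = {v:g}")
        for r in self.reasons:
            lines.append(f"    ! {r}")
        return lines


def rna_purity_qc(a260_a280: float, a260_a230: float) -> GateResult:
    """Absorbance-ratio purity gate."""
    if a260_a280 <= 0 or a260_a230 <= 0:
        raise ValidationError("absorbance ratios must be positive")
    reasons = []
    if not (A260_A280_LO <= a260_a280 <= A260_A280_HI):
        reasons.append(
            f"A260/A280 = {a260_a280:g} outside [{A260_A280_LO}, {A260_A280_HI}]"
        )
    if not (a260_a230 > A260_A230_MIN):
        reasons.append(f"A260/A230 = {a260_a230:g} not above {A260_A230_MIN}")
    return GateResult(
        name="rna_purity",
        passed=not reasons,
        reasons=reasons,
        metrics={"a260_a280": a260_a280, "a260_a230": a260_a230},
    )


def specific_activity(dye_pmol_per_ul: float, crna_ug_per_ul: float) -> float:
    """pmol dye per ug cRNA: the quotient of the two concentrations."""
    if crna_ug_per_ul <= 0:
        raise ValidationError("cRNA concentration must be positive")
    if dye_pmol_per_ul < 0:
        raise ValidationError("dye concentration must be nonnegative")
    return dye_pmol_per_ul / crna_ug_per_ul


def labeling_qc(
    mode: str,
    yield_ng: float,
    dye_pmol_per_ul: float,
    crna_ug_per_ul: float,
    strict: bool = False,
) -> GateResult:
    """Hybridization go/no-go gate on labeling yield and specific activity.

    ``passed`` means "proceed to hybridization". Thresholds are strict
    below: a value exactly at the boundary is not low.
    """
    if mode not in ("one_color", "two_color"):
        raise ValidationError("mode must be 'one_color' or 'two_color'")
    if yield_ng < 0:
        raise ValidationError("yield must be nonnegative")
    sa = specific_activity(dye_pmol_per_ul, crna_ug_per_ul)
    if mode == "two_color":
        y_thr, sa_thr = TWO_COLOR_YIELD_NG, TWO_COLOR_SA
    else:
        y_thr, sa_thr = ONE_COLOR_YIELD_NG, ONE_COLOR_SA
    low_yield = yield_ng < y_thr
    low_sa = sa < sa_thr
    stop = (low_yield or low_sa) if strict else (low_yield and low_sa)
    reasons = []
    if low_yield:
        reasons.append(f"yield {yield_ng:g} ng below {y_thr:g} ng")
    if low_sa:
        reasons.append(f"specific activity {sa:g} below {sa_thr:g} pmol/ug")
    if stop:
        reasons.append("hybridization not carried out")
    return GateResult(
        name=f"labeling_{mode}",
        passed=not stop,
        reasons=reasons,
        metrics={
            "yield_ng": yield_ng,
            "specific_activity": sa,
            "yield_threshold_ng": y_thr,
            "specific_activity_threshold": sa_thr,
        },
    )


def merip_spikein_qc(
    pos_enrichment: float,
    neg_enrichment: float,
    min_ratio: float = SPIKE_RATIO_DEFAULT,
) -> GateResult:
    """Capture-efficiency gate: positive/negative spike enrichment ratio.

    Passes when the ratio meets ``min_ratio`` (inclusive bound).
    """
    if pos_enrichment < 0 or neg_enrichment < 0:
        raise ValidationError("enrichments must be nonnegative")
    ratio = pos_enrichment / max(neg_enrichment, _EPS)
    passed = ratio >= min_ratio
    reasons = (
        []
        if passed
        else [f"pos/neg enrichment ratio {ratio:g} below {min_ratio:g}"]
    )
    return GateResult(
        name="merip_spikein",
        passed=passed,
        reasons=reasons,
        metrics={
            "pos_enrichment": pos_enrichment,
            "neg_enrichment": neg_enrichment,
            "ratio": ratio,
            "min_ratio": min_ratio,
        },
    )


def qc_summary(results: list[GateResult]) -> tuple[str, dict]:
    """Render gates as a text block and a machine-readable mapping."""
    lines: list[str] = ["QC summary", "=========="]
    record: dict[str, dict] = {}
    for res in results:
        lines.extend(res.summary_lines())
        record[res.name] = {
            "passed": res.passed,
            "reasons": list(res.reasons),
            "metrics": dict(res.metrics),
        }
    return "\n".join(lines) + "\n", record
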