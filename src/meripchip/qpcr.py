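"""MeRIP-qPCR validation analysis.

After immunoprecipitation, the captured (IP) fraction and a reserved
input aliquot are quantified by qPCR. Enrichment is expressed as percent
of input with the standard dilution correction:

    adjusted input Ct = ct_input - log2(1 / input_fraction)
    %input           = 100 * 2^(adjusted input Ct - ct_ip)

The protocol states input normalization but not the reserved fraction;
the default here is 0.1 and must be set to the experiment's true value.
Amplification efficiency is assumed to be a perfect doubling per cycle.

Replicates (three per sample by design) are combined by the arithmetic
mean of %input — the quantity compared downstream — and each target's
%input is then divided by the same sample's positive-control (CTA850)
%input, with the negative control (CTA650) reported as the background
floor. Samples whose spike controls fail the capture-efficiency gate are
flagged and excluded from group comparisons by default. Groups are
compared by a two-sided Welch t-test with the figure-legend star code.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .containers import GROUP_CASE, GROUP_CONTROL
from .differential import welch_p
from .errors import ValidationError
from .qc import SPIKE_RATIO_DEFAULT, merip_spikein_qc

POSITIVE_CONTROL = "CTA850"
NEGATIVE_CONTROL = "CTA650"
CONTROL_TARGETS = (POSITIVE_CONTROL, NEGATIVE_CONTROL)

QPCR_COLUMNS = ("sample_id", "group", "target_id", "role", "replicate", "ct")
INPUT_FRACTION_DEFAULT = 0.1

#: Star codes as in the validation figure legend; a single star for
#: p < 0.05 completes the conventional scale.
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def percent_input(ct_ip, ct_input, input_fraction: float = INPUT_FRACTION_DEFAULT):
    """%input from paired IP / input Ct values (scalar or array)."""
    if not (0.0 < input_fraction <= 1.0):
        raise ValidationError("input_fraction must be in (0, 1]")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    if (ct_ip <= 0).any() or (ct_input <= 0).any():
        raise ValidationError("Ct values must be positive")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    out = 100.0 * np.exp2(adjusted - ct_ip)
    return float(out) if out.ndim == 0 else out


def star_code(p: float) -> str:
    """Figure-legend significance stars as a pure threshold function."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p must be in [0, 1]")
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"qPCR table is missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    bad_roles = sorted(set(table["role"]) - {"IP", "input"})
    if bad_roles:
        raise ValidationError(f"unknown qPCR roles: {bad_roles}")
    return table


def summarize_percent_input(
    table: pd.DataFrame, input_fraction: float = INPUT_FRACTION_DEFAULT
) -> pd.DataFrame:
    """Replicate-mean %input per (sample, target).

    IP and input Ct values are paired replicate-wise, converted to
    %input, and averaged over replicates.
    """
    validate_qpcr_table(table)
    wide = table.pivot_table(
        index=["sample_id", "group", "target_id", "replicate"],
        columns="role",
        values="ct",
    )
    if "IP" not in wide.columns or "input" not in wide.columns:
        raise ValidationError("table needs both IP and input rows")
    if wide[["IP", "input"]].isna().any().any():
        incomplete = wide[wide[["IP", "input"]].isna().any(axis=1)]
        raise ValidationError(
            f"unpaired IP/input replicates, e.g. {list(incomplete.index[:3])}"
        )
    pct = percent_input(
        wide["IP"].to_numpy(), wide["input"].to_numpy(), input_fraction
    )
    wide = wide.assign(pct_input=pct).reset_index()
    out = (
        wide.groupby(["sample_id", "group", "target_id"], sort=False)["pct_input"]
        .mean()
        .reset_index()
    )
    return out


def control_normalize(
    table: pd.DataFrame,
    input_fraction: float = INPUT_FRACTION_DEFAULT,
    min_ratio: float = SPIKE_RATIO_DEFAULT,
) -> pd.DataFrame:
    """Per-sample relative enrichment against the positive spike control.

    Adds ``rel_enrichment`` (%input / sample's CTA850 %input),
    ``neg_floor_pct`` (the sample's CTA650 %input) and ``sample_qc_pass``
    from the capture-efficiency gate.
    """
    summary = summarize_percent_input(table, input_fraction)
    rows = []
    for sample_id, block in summary.groupby("sample_id", sort=False):
        targets = dict(zip(block["target_id"], block["pct_input"]))
        for ctrl in CONTROL_TARGETS:
            if ctrl not in targets:
                raise ValidationError(
                    f"sample {sample_id!r} is missing control target {ctrl}"
                )
        pos = targets[POSITIVE_CONTROL]
        neg = targets[NEGATIVE_CONTROL]
        qc_pass = merip_spikein_qc(pos, neg, min_ratio).passed
        block = block.assign(
            rel_enrichment=block["pct_input"] / pos,
            neg_floor_pct=neg,
            sample_qc_pass=qc_pass,
        )
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class GroupComparison:
    """Welch comparison of one target's relative enrichment across groups."""

    target_id: str
    group1: str
    group2: str
    n_group1: int
    n_group2: int
    mean_group1: float
    mean_group2: float
    direction: str  # higher / lower / equal in group2 vs group1
    p_value: float
    stars: str


def group_compare(
    normalized: pd.DataFrame,
    target_id: str,
    group1: str = GROUP_CONTROL,
    group2: str = GROUP_CASE,
    exclude_flagged: bool = True,
) -> GroupComparison:
    """Compare per-sample relative enrichment of one target between groups."""
    block = normalized[normalized["target_id"] == target_id]
    if block.empty:
        raise ValidationError(f"target {target_id!r} not in the table")
    if exclude_flagged and "sample_qc_pass" in block.columns:
        block = block[block["sample_qc_pass"]]
    g1 = block.loc[block["group"] == group1, "rel_enrichment"].to_numpy(float)
    g2 = block.loc[block["group"] == group2, "rel_enrichment"].to_numpy(float)
    if g1.size < 2 or g2.size < 2:
        raise ValidationError(
            f"target {target_id!r}: need >= 2 usable samples per group "
            f"(found {g1.size} vs {g2.size})"
        )
    p = welch_p(g1, g2)
    m1, m2 = float(g1.mean()), float(g2.mean())
    direction = "higher" if m2 > m1 else ("lower" if m2 < m1 else "equal")
    return GroupComparison(
        target_id=target_id,
        group1=group1,
        group2=group2,
        n_group1=int(g1.size),
        n_group2=int(g2.size),
        mean_group1=m1,
        mean_group2=m2,
        direction=direction,
        p_value=p,
        stars=star_code(p),
    )


def compare_all_targets(normalized: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Group comparison for every non-control target, as a table."""
    targets = [
        t
        for t in normalized["target_id"].drop_duplicates()
        if t not in CONTROL_TARGETS
    ]
    recs = [dataclasses.asdict(group_compare(normalized, t, **kwargs)) for t in targets]
    return pd.DataFrame(recs)
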