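"""Spike-in anchored normalization and per-transcript m6A quantification.

Each channel is normalized per sample against the average of the
log2-scaled spike-in intensities of that channel:

    normalized(p, s) = log2(raw(p, s)) - mean_spike log2(raw(spike, s))

The subtraction cancels any sample- and channel-wide multiplicative factor
(dye incorporation, labeling yield, scanner gain), which is the point of
carrying exogenous spikes of known methylation status. The IP (Cy5)
channel is anchored on the methylation-positive spikes; the supernatant
(Sup, Cy3) channel is anchored analogously on the negative spikes, which
are recovered in the unmethylated fraction. ``spike_probes="all"`` uses
both classes for both channels instead.

From the two normalized channels, three per-transcript quantities follow:

- m6A quantity  = normalized IP intensity (log2), the methylation amount;
- m6A percentage = 100 * IP / (IP + Sup) on the linear scale, i.e. the
  fraction of a transcript's molecules that were captured;
- expression    = log2(IP + Sup), the total abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, QuantTable
from .design import ArrayDesign
from .errors import AlignmentError, ValidationError

DEFAULT_FLOOR = 1.0


def normalize_channel(
    raw: IntensityMatrix,
    design: ArrayDesign,
    spike_probes: str = "matched",
    floor: float = DEFAULT_FLOOR,
) -> IntensityMatrix:
    """Normalize one raw channel to its spike-in average (log2 scale).

    Intensities are floored at ``floor`` (default 1.0) before the log2
    transform so zero intensities map to 0 rather than -inf. Spike-in
    rows are retained in the output.
    """
    if raw.scale != "raw":
        raise ValidationError("normalize_channel expects a raw-scale matrix")
    if spike_probes == "matched":
        spike_ids = design.spike_probe_ids(raw.channel)
    elif spike_probes == "all":
        spike_ids = design.probe_ids("spike_pos") + design.probe_ids("spike_neg")
    else:
        raise ValidationError("spike_probes must be 'matched' or 'all'")
    spike_ids = [p for p in spike_ids if p in raw.values.index]
    if not spike_ids:
        raise ValidationError(
            f"no usable spike-in probes for channel {raw.channel}"
        )
    log2 = np.log2(np.maximum(raw.values, floor))
    anchor = log2.loc[spike_ids].mean(axis=0)
    return IntensityMatrix(
        values=log2.sub(anchor, axis=1),
        groups=dict(raw.groups),
        channel=raw.channel,
        scale="normalized",
    )


def transcript_level(norm: IntensityMatrix, design: ArrayDesign) -> pd.DataFrame:
    """Collapse a normalized probe matrix to mRNA transcript level.

    Spike-in (and any non-mRNA) rows are dropped. The default design maps
    probes to transcripts 1:1; if several probes share a transcript their
    linear intensities are averaged before re-logging.
    """
    if norm.scale != "normalized":
        raise ValidationError("transcript_level expects a normalized matrix")
    probe2tx = design.transcript_of()
    probes = [p for p in norm.values.index if p in probe2tx.index]
    sub = norm.values.loc[probes]
    tx = probe2tx.loc[probes].values
    linear = pd.DataFrame(
        np.exp2(sub.to_numpy()), index=tx, columns=sub.columns
    )
    collapsed = np.log2(linear.groupby(level=0, sort=False).mean())
    collapsed.index.name = "transcript_id"
    return collapsed


def m6a_quantity(ip_norm: IntensityMatrix, design: ArrayDesign) -> pd.DataFrame:
    """The methylation-amount statistic: normalized log2 IP per transcript."""
    if ip_norm.channel != "IP":
        raise ValidationError("m6a_quantity expects the IP channel")
    return transcript_level(ip_norm, design)


def _check_aligned(ip: pd.DataFrame, sup: pd.DataFrame) -> None:
    if not (ip.index.equals(sup.index) and ip.columns.equals(sup.columns)):
        raise AlignmentError("IP and Sup tables are not aligned")


def m6a_percentage(ip: pd.DataFrame, sup: pd.DataFrame) -> pd.DataFrame:
    """Percent of molecules methylated: 100 * 2^ip / (2^ip + 2^sup).

    Depends only on the difference ip - sup and increases strictly with
    it, reaching 50 when the channels are equal.
    """
    _check_aligned(ip, sup)
    delta = sup.to_numpy() - ip.to_numpy()
    pct = 100.0 / (1.0 + np.exp2(delta))
    return pd.DataFrame(pct, index=ip.index, columns=ip.columns)


def expression_level(ip: pd.DataFrame, sup: pd.DataFrame) -> pd.DataFrame:
    """Total abundance: log2(2^ip + 2^sup), computed stably."""
    _check_aligned(ip, sup)
    expr = np.logaddexp2(ip.to_numpy(), sup.to_numpy())
    return pd.DataFrame(expr, index=ip.index, columns=ip.columns)


def quantify(
    ip_raw: IntensityMatrix,
    sup_raw: IntensityMatrix,
    design: ArrayDesign,
    spike_probes: str = "matched",
    floor: float = DEFAULT_FLOOR,
) -> QuantTable:
    """Normalize both channels and compute the three per-transcript tables."""
    if ip_raw.channel != "IP" or sup_raw.channel != "Sup":
        raise ValidationError("quantify expects (IP, Sup) raw matrices")
    ip_t = transcript_level(
        normalize_channel(ip_raw, design, spike_probes, floor), design
    )
    sup_t = transcript_level(
        normalize_channel(sup_raw, design, spike_probes, floor), design
    )
    _check_aligned(ip_t, sup_t)
    return QuantTable(
        m6a_quantity=ip_t,
        m6a_pct=m6a_percentage(ip_t, sup_t),
        expression=expression_level(ip_t, sup_t),
        groups=dict(ip_raw.groups),
    )


def write_quant_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# scale=normalized\n")
        df.to_csv(fh, sep="\t")


def read_quant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index.name = "transcript_id"
    return df
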