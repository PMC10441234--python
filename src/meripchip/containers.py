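"""In-memory containers for probe-level and transcript-level matrices.

An :class:`IntensityMatrix` holds one channel of a two-color experiment
(IP/Cy5, the immunoprecipitated methylated fraction; or Sup/Cy3, the
supernatant) as a probes x samples table, either on the raw linear scale
or spike-in normalized on the log2 scale. Sample names carry group
membership (``chol_*`` cases, ``skin_*`` controls by convention), which is
kept alongside as an explicit mapping so other naming schemes work too.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

GROUP_CASE = "cholesteatoma"
GROUP_CONTROL = "skin"

CHANNELS = ("IP", "Sup")
SCALES = ("raw", "normalized")


def infer_groups(samples) -> dict[str, str]:
    """Map sample names to group labels by name prefix.

    ``chol_*`` -> cholesteatoma, ``skin_*`` -> skin; anything else keeps
    the part before the last underscore as its group label.
    """
    out = {}
    for s in samples:
        if s.startswith("chol"):
            out[s] = GROUP_CASE
        elif s.startswith("skin"):
            out[s] = GROUP_CONTROL
        else:
            out[s] = s.rsplit("_", 1)[0]
    return out


@dataclasses.dataclass(eq=False)
class IntensityMatrix:
    """One channel's probes x samples intensities plus group labels."""

    values: pd.DataFrame
    groups: dict[str, str]
    channel: str
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group labels: {missing}")
        if self.scale == "raw":
            vals = self.values.to_numpy()
            if not np.isfinite(vals).all():
                raise FormatError("raw intensities must be finite")
            if (vals < 0).any():
                raise FormatError("raw intensities must be nonnegative")
        self.values.index.name = "probe_id"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityMatrix):
            return NotImplemented
        return (
            self.channel == other.channel
            and self.scale == other.scale
            and self.groups == other.groups
            and self.values.equals(other.values)
        )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# channel={self.channel}\n# scale={self.scale}\n")
            self.values.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path, groups: dict[str, str] | None = None) -> "IntensityMatrix":
        meta = {}
        skip = 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        if "channel" not in meta:
            raise FormatError(f"{path}: missing '# channel=' header")
        df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
        df.columns = [str(c) for c in df.columns]
        return cls(
            values=df,
            groups=groups or infer_groups(df.columns),
            channel=meta["channel"],
            scale=meta.get("scale", "raw"),
        )


@dataclasses.dataclass(eq=False)
class QuantTable:
    """Per transcript x sample quantification results (all aligned).

    - ``m6a_quantity``: spike-in normalized log2 IP intensity, the study's
      per-transcript methylation-amount statistic.
    - ``m6a_pct``: estimated percentage of molecules carrying m6A, in
      [0, 100], from the IP/Sup partition.
    - ``expression``: log2 of the total (IP + Sup) normalized intensity.
    """

    m6a_quantity: pd.DataFrame
    m6a_pct: pd.DataFrame
    expression: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.m6a_quantity.index
        cols = self.m6a_quantity.columns
        for name in ("m6a_pct", "expression"):
            df = getattr(self, name)
            if not (df.index.equals(idx) and df.columns.equals(cols)):
                raise ValidationError(f"{name} is not aligned with m6a_quantity")
        for df in (self.m6a_quantity, self.m6a_pct, self.expression):
            df.index.name = "transcript_id"
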