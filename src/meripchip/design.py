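"""Array manifest for the two-color m6A epitranscriptomic microarray.

The array interrogates each mRNA with one probe. The hybridization mix
additionally carries exogenous spike-in RNAs of known methylation status:
fully methylated "positive" spikes (CTA850 analogues) that are captured in
the immunoprecipitated (IP, Cy5) fraction, and unmethylated "negative"
spikes (CTA650 analogues) recovered in the supernatant (Sup, Cy3) fraction.
Spike-ins anchor the per-sample channel normalization, so every valid
design must contain at least one probe of each spike class.

The default design mirrors the commercial 8 x 60 K human epitranscriptomic
array content of 35,175 mRNA probes. Synthetic transcript ids are
deterministic (``ENSTSIM`` + zero-padded index) so fixtures are stable
across runs; the five MeRIP-qPCR-validated transcripts are injected
verbatim at fixed manifest positions.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .errors import FormatError, ValidationError

PROBE_CLASSES = ("mRNA", "lncRNA", "spike_pos", "spike_neg")
DESIGN_COLUMNS = ("probe_id", "transcript_id", "gene_symbol", "probe_class")

DEFAULT_N_MRNA = 35175
DEFAULT_N_SPIKE = 8

#: Transcripts validated by MeRIP-qPCR, with gene symbols, injected into the
#: default design at :data:`VALIDATED_POSITIONS`.
VALIDATED_TRANSCRIPTS = (
    ("ENST00000266557", "CD27"),
    ("ENST00000537824", "CSMD1"),
    ("ENST00000258499", "USP44"),
    ("ENST00000436547", "TIAL1"),
    ("ENST00000536621", "MUC12"),
)
#: Fixed manifest positions for the validated transcripts. The two
#: hypermethylated genes sit near the manifest front and the three
#: hypomethylated ones just past position 4,620, so a study-scale
#: simulation (hyper block first, hypo block second) realizes the same
#: directions the validation table reports.
VALIDATED_POSITIONS = (11, 23, 4650, 4700, 4750)

#: Microarray calls for the validated transcripts as printed in the source
#: study's validation table: (transcript_id, gene_symbol, fold_change,
#: p_value, regulation). Used as a worked classification example.
VALIDATED_MICROARRAY_CALLS = (
    ("ENST00000266557", "CD27", 3.270, 0.0009, "hyper"),
    ("ENST00000537824", "CSMD1", 4.559, 0.0020, "hyper"),
    ("ENST00000258499", "USP44", 0.001, 0.0000, "hypo"),
    ("ENST00000436547", "TIAL1", 0.023, 0.0004, "hypo"),
    ("ENST00000536621", "MUC12", 0.002, 0.0000, "hypo"),
)


@dataclasses.dataclass(eq=False)
class ArrayDesign:
    """Probe manifest: one row per probe, validated on construction.

    ``probes`` columns: probe_id, transcript_id, gene_symbol, probe_class.
    """

    probes: pd.DataFrame
    design_name: str = "sim-epitx-8x60k"

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.probes
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"design is missing columns: {missing}")
        bad = sorted(set(df["probe_class"]) - set(PROBE_CLASSES))
        if bad:
            raise FormatError(f"unknown probe_class values: {bad}")
        dup = df["probe_id"][df["probe_id"].duplicated()]
        if len(dup):
            raise FormatError(
                f"duplicate probe_id values: {sorted(set(dup))[:5]}"
            )
        for cls in ("spike_pos", "spike_neg"):
            if not (df["probe_class"] == cls).any():
                raise ValidationError(f"design contains no {cls} probes")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayDesign):
            return NotImplemented
        return self.design_name == other.design_name and self.probes.equals(
            other.probes
        )

    @property
    def mrna(self) -> pd.DataFrame:
        return self.probes[self.probes["probe_class"] == "mRNA"]

    def probe_ids(self, probe_class: str) -> list[str]:
        return list(
            self.probes.loc[self.probes["probe_class"] == probe_class, "probe_id"]
        )

    def spike_probe_ids(self, channel: str) -> list[str]:
        """Spike probes anchoring normalization of ``channel`` (IP or Sup).

        Positive (methylated) spikes are recovered in the IP fraction,
        negative (unmethylated) spikes in the supernatant.
        """
        if channel == "IP":
            return self.probe_ids("spike_pos")
        if channel == "Sup":
            return self.probe_ids("spike_neg")
        raise ValidationError(f"unknown channel {channel!r}")

    def transcript_of(self) -> pd.Series:
        """probe_id -> transcript_id map restricted to mRNA probes."""
        m = self.mrna
        return pd.Series(m["transcript_id"].values, index=m["probe_id"].values)

    def gene_symbol_of(self) -> pd.Series:
        """transcript_id -> gene_symbol map restricted to mRNA probes."""
        m = self.mrna.drop_duplicates("transcript_id")
        return pd.Series(m["gene_symbol"].values, index=m["transcript_id"].values)


def default_design(
    n_mrna: int = DEFAULT_N_MRNA,
    n_spike_pos: int = DEFAULT_N_SPIKE,
    n_spike_neg: int = DEFAULT_N_SPIKE,
    design_name: str = "sim-epitx-8x60k",
) -> ArrayDesign:
    """Deterministic synthetic manifest emulating the commercial array.

    ``n_mrna`` mRNA probes (default 35,175) plus configurable counts of
    positive/negative spike-in probes. The five validated transcript ids
    replace synthetic ids at fixed positions when the design is large
    enough to hold them.
    """
    if n_mrna < 1 or n_spike_pos < 1 or n_spike_neg < 1:
        raise ValidationError("need at least one mRNA and one spike of each class")
    probe_id = [f"PSIM{i:06d}" for i in range(n_mrna)]
    transcript_id = [f"ENSTSIM{i:08d}" for i in range(n_mrna)]
    gene_symbol = [f"GSIM{i:05d}" for i in range(n_mrna)]
    if n_mrna > max(VALIDATED_POSITIONS):
        for (tid, sym), pos in zip(VALIDATED_TRANSCRIPTS, VALIDATED_POSITIONS):
            transcript_id[pos] = tid
            gene_symbol[pos] = sym
    rows = {
        "probe_id": probe_id
        + [f"SPIKE_POS_{k:02d}" for k in range(n_spike_pos)]
        + [f"SPIKE_NEG_{k:02d}" for k in range(n_spike_neg)],
        "transcript_id": transcript_id
        + [f"CTA850_{k:02d}" for k in range(n_spike_pos)]
        + [f"CTA650_{k:02d}" for k in range(n_spike_neg)],
        "gene_symbol": gene_symbol
        + ["CTA850"] * n_spike_pos
        + ["CTA650"] * n_spike_neg,
        "probe_class": ["mRNA"] * n_mrna
        + ["spike_pos"] * n_spike_pos
        + ["spike_neg"] * n_spike_neg,
    }
    return ArrayDesign(pd.DataFrame(rows), design_name=design_name)


def write_design(design: ArrayDesign, path) -> None:
    design.probes.loc[:, list(DESIGN_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_design(path, design_name: str | None = None) -> ArrayDesign:
    """Read a TSV manifest; raises on duplicates or missing spike classes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != list(DESIGN_COLUMNS):
        raise FormatError(
            f"expected header {list(DESIGN_COLUMNS)}, found {list(df.columns)}"
        )
    return ArrayDesign(df, design_name=design_name or str(path))
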