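"""Synthetic two-color MeRIP microarray experiments with planted truth.

The generator emulates the study design: two groups of five samples
(cholesteatoma cases vs post-auricular skin controls), 35,175 mRNA
probes, positive/negative spike-in controls, and planted hyper/hypo
methylation and up/down expression effects.

Generative model (per transcript t, sample s):

- baseline copy number   A0 = 2^(baseline_log2 + e(t)·case(s) + z·noise_sd)
  with e(t) the log2 expression effect and z a standard normal draw —
  log2-additive Gaussian noise, i.e. log-normal on the linear scale;
- methylated fraction    f0 = meth_fraction_baseline at baseline;
- methylation effect     multiplies the *methylated copy number*:
  M = A0·f0·m(t), U = A0·(1-f0), with m(t) the planted ratio in cases.
  Equivalently the odds of the methylated fraction are multiplied by
  m(t) (realized fraction f = f0·m/(1-f0+f0·m)), while the total
  abundance becomes A0·(1-f0+f0·m).

This makes the realized IP ratio equal the planted methylation ratio
exactly in the noise-free limit, at the cost of two couplings that are
faithful to the assay chemistry: methylation changes total abundance by
1-f0+f0·m, and expression changes propagate into the IP channel. For
that reason :class:`SimTruth` reports, per transcript, both the planted
labels and the *realized* noise-free ratios, with recovery labels
derived from the realized ratios at the standard calling thresholds.

IP raw = M, Sup raw = U, each times a per-sample per-channel scale
factor (dye/labeling efficiency; defaults to 1) that the spike-in
normalization must cancel. Positive spikes appear in the IP channel at
spike_level_log2 with the same noise model and only at background in
the supernatant; negative spikes mirror this.

Randomness: one integer seed drives separate named substreams (one per
noise source) via ``numpy`` SeedSequence spawn keys. Abundance noise is
drawn as a (transcripts x samples) block in row-major order, so
enlarging the design extends the draw without perturbing earlier rows.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .containers import GROUP_CASE, GROUP_CONTROL, IntensityMatrix
from .design import ArrayDesign, default_design
from .differential import FC_HI_DEFAULT, FC_LO_DEFAULT
from .errors import ValidationError

# Named noise substreams.
_STREAM_ABUNDANCE = 0
_STREAM_SPIKE_POS = 1
_STREAM_SPIKE_NEG = 2
_STREAM_SCALE_IP = 3
_STREAM_SCALE_SUP = 4
_STREAM_QPCR = 5

QPCR_POS_FRACTION = 0.9
QPCR_NEG_FRACTION = 0.01
QPCR_CT_BASE = 20.0


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror the study design where it states one (5 samples per
    group, planted ratios 4.0 for hypermethylation and 0.25 for
    downregulation with reciprocals for the opposite directions) and a
    field-realistic stand-in where it does not (log2 noise SD 0.25,
    baseline methylated fraction 0.5, baseline log2 intensity 10).
    """

    n_transcripts: int | None = None  # None: take from the design
    n_per_group: int = 5
    n_hyper: int = 0
    n_hypo: int = 0
    n_up: int = 0
    n_down: int = 0
    true_meth_fc: float = 4.0  # planted hyper ratio; hypo gets 1/this
    true_expr_fc: float = 0.25  # planted down ratio; up gets 1/this
    noise_sd: float = 0.25
    baseline_log2: float = 10.0
    meth_fraction_baseline: float = 0.5
    spike_level_log2: float = 10.0
    scale_log2_min: float = 0.0  # per-sample per-channel log2 scale range
    scale_log2_max: float = 0.0
    background: float = 1.0  # off-channel spike intensity
    seed: int = 0

    def validate(self, n_design: int | None = None) -> None:
        if self.n_transcripts is not None and self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be positive")
        n = self.n_transcripts if self.n_transcripts is not None else n_design
        if n_design is not None and self.n_transcripts is not None:
            if self.n_transcripts != n_design:
                raise ValidationError(
                    f"cfg.n_transcripts={self.n_transcripts} does not match "
                    f"the design's {n_design} mRNA probes"
                )
        for name in ("n_per_group", "n_hyper", "n_hypo", "n_up", "n_down"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be at least 1")
        if n is not None:
            if self.n_hyper + self.n_hypo > n:
                raise ValidationError("n_hyper + n_hypo exceeds n_transcripts")
            if self.n_up + self.n_down > n:
                raise ValidationError("n_up + n_down exceeds n_transcripts")
            if self.n_hyper + self.n_hypo + self.n_up + self.n_down > n:
                raise ValidationError(
                    "planted effect blocks (disjoint) exceed n_transcripts"
                )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.true_meth_fc <= 0 or self.true_expr_fc <= 0:
            raise ValidationError("planted ratios must be positive")
        if not (0.0 < self.meth_fraction_baseline < 1.0):
            raise ValidationError("meth_fraction_baseline must be in (0, 1)")
        if self.scale_log2_min > self.scale_log2_max:
            raise ValidationError("scale_log2_min must be <= scale_log2_max")
        if self.background < 0:
            raise ValidationError("background must be nonnegative")


def study_config(seed: int = 0) -> SimConfig:
    """Full study-scale conditions: 35,175 mRNAs, 5 vs 5 samples, planted
    counts equal to the study's reported differential counts."""
    return SimConfig(
        n_transcripts=None,
        n_per_group=5,
        n_hyper=4620,
        n_hypo=2245,
        n_up=4891,
        n_down=4271,
        seed=seed,
    )


def _normals(seed: int, stream: int, shape) -> np.ndarray:
    ss = np.random.SeedSequence(seed, spawn_key=(stream,))
    return np.random.default_rng(ss).standard_normal(shape)


def _uniform(seed: int, stream: int, lo: float, hi: float, size: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed, spawn_key=(stream,))
    return np.random.default_rng(ss).uniform(lo, hi, size)


def sample_names(n_per_group: int) -> tuple[list[str], dict[str, str]]:
    chol = [f"chol_{i + 1}" for i in range(n_per_group)]
    skin = [f"skin_{i + 1}" for i in range(n_per_group)]
    groups = {s: GROUP_CASE for s in chol}
    groups.update({s: GROUP_CONTROL for s in skin})
    return chol + skin, groups


def _planted_labels(n: int, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint index blocks: hyper, hypo, up, down, in manifest order."""
    meth = np.full(n, "none", dtype=object)
    expr = np.full(n, "none", dtype=object)
    i = 0
    meth[i : i + cfg.n_hyper] = "hyper"
    i += cfg.n_hyper
    meth[i : i + cfg.n_hypo] = "hypo"
    i += cfg.n_hypo
    expr[i : i + cfg.n_up] = "up"
    i += cfg.n_up
    expr[i : i + cfg.n_down] = "down"
    return meth, expr


def _derived_label(ratio: np.ndarray, hi: float, lo: float, labels) -> np.ndarray:
    out = np.full(ratio.shape, "none", dtype=object)
    out[ratio >= hi] = labels[0]
    out[ratio <= lo] = labels[1]
    return out


def simulate_experiment(
    design: ArrayDesign, cfg: SimConfig
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame]:
    """Generate (ip_raw, sup_raw, truth) for one two-color experiment.

    Bit-identical for identical (design, cfg); see the module docstring
    for the generative model and the SimTruth columns.
    """
    mrna = design.mrna
    n_t = len(mrna)
    cfg.validate(n_design=n_t)
    samples, groups = sample_names(cfg.n_per_group)
    n_s = len(samples)
    is_case = np.array([1.0 if groups[s] == GROUP_CASE else 0.0 for s in samples])

    planted_meth, planted_expr = _planted_labels(n_t, cfg)
    e_log2 = np.zeros(n_t)
    e_log2[planted_expr == "up"] = -math.log2(cfg.true_expr_fc)
    e_log2[planted_expr == "down"] = math.log2(cfg.true_expr_fc)
    m_mult = np.ones(n_t)
    m_mult[planted_meth == "hyper"] = cfg.true_meth_fc
    m_mult[planted_meth == "hypo"] = 1.0 / cfg.true_meth_fc

    z = _normals(cfg.seed, _STREAM_ABUNDANCE, (n_t, n_s))
    log2_A0 = (
        cfg.baseline_log2
        + np.outer(e_log2, is_case)
        + z * cfg.noise_sd
    )
    A0 = np.exp2(log2_A0)
    f0 = cfg.meth_fraction_baseline
    mult = 1.0 + np.outer(m_mult - 1.0, is_case)  # m(t) in cases, 1 in controls
    M = A0 * f0 * mult
    U = A0 * (1.0 - f0)

    scale_ip = np.exp2(
        _uniform(cfg.seed, _STREAM_SCALE_IP, cfg.scale_log2_min, cfg.scale_log2_max, n_s)
    )
    scale_sup = np.exp2(
        _uniform(cfg.seed, _STREAM_SCALE_SUP, cfg.scale_log2_min, cfg.scale_log2_max, n_s)
    )

    pos_ids = design.probe_ids("spike_pos")
    neg_ids = design.probe_ids("spike_neg")
    z_pos = _normals(cfg.seed, _STREAM_SPIKE_POS, (len(pos_ids), n_s))
    z_neg = _normals(cfg.seed, _STREAM_SPIKE_NEG, (len(neg_ids), n_s))
    spike_pos_ip = np.exp2(cfg.spike_level_log2 + z_pos * cfg.noise_sd)
    spike_neg_sup = np.exp2(cfg.spike_level_log2 + z_neg * cfg.noise_sd)
    bg_pos = np.full((len(pos_ids), n_s), cfg.background)
    bg_neg = np.full((len(neg_ids), n_s), cfg.background)

    probe_ids = list(mrna["probe_id"]) + pos_ids + neg_ids
    ip_vals = np.vstack([M, spike_pos_ip, bg_neg]) * scale_ip
    sup_vals = np.vstack([U, bg_pos, spike_neg_sup]) * scale_sup
    order = list(design.probes["probe_id"])
    ip_df = pd.DataFrame(ip_vals, index=probe_ids, columns=samples).loc[order]
    sup_df = pd.DataFrame(sup_vals, index=probe_ids, columns=samples).loc[order]

    ip = IntensityMatrix(ip_df, dict(groups), channel="IP", scale="raw")
    sup = IntensityMatrix(sup_df, dict(groups), channel="Sup", scale="raw")

    # Noise-free realized ratios (case/control) and fractions.
    e_ratio = np.exp2(e_log2)
    true_meth_ratio = e_ratio * m_mult
    total_factor = 1.0 - f0 + f0 * m_mult
    true_expr_ratio = e_ratio * total_factor
    f_case = f0 * m_mult / total_factor
    truth = pd.DataFrame(
        {
            "planted_meth": planted_meth,
            "planted_expr": planted_expr,
            "true_meth_ratio": true_meth_ratio,
            "true_expr_ratio": true_expr_ratio,
            "true_m6a_pct_control": 100.0 * f0,
            "true_m6a_pct_case": 100.0 * f_case,
            "meth_label": _derived_label(
                true_meth_ratio, FC_HI_DEFAULT, FC_LO_DEFAULT, ("hyper", "hypo")
            ),
            "expr_label": _derived_label(
                true_expr_ratio, FC_HI_DEFAULT, FC_LO_DEFAULT, ("up", "down")
            ),
        },
        index=pd.Index(list(mrna["transcript_id"]), name="transcript_id"),
    )
    return ip, sup, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def simulate_qpcr(
    truth: pd.DataFrame,
    transcripts: list[str],
    cfg: SimConfig,
    n_per_group: int = 10,
    n_replicates: int = 3,
    input_fraction: float = 0.1,
    ct_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Simulate a MeRIP-qPCR Ct table for selected transcripts.

    The validation cohort (default 10 samples per group, 3 replicates)
    is independent of the array samples. Ct values follow the ideal
    doubling model ct = ct_base - log2(quantity) around the transcript's
    realized methylated fraction and total abundance, plus Gaussian
    cycle noise (default SD: cfg.noise_sd). Control targets CTA850
    (captured fraction 0.9) and CTA650 (0.01) are emitted for every
    sample. Same seed, same table.
    """
    missing = [t for t in transcripts if t not in truth.index]
    if missing:
        raise ValidationError(f"transcripts not in the truth table: {missing}")
    if not (0.0 < input_fraction <= 1.0):
        raise ValidationError("input_fraction must be in (0, 1]")
    if n_per_group < 1 or n_replicates < 1:
        raise ValidationError("need at least 1 sample and 1 replicate")
    sd = cfg.noise_sd if ct_noise_sd is None else ct_noise_sd

    targets = list(transcripts) + [
        "CTA850",
        "CTA650",
    ]
    frac = {}
    total = {}
    for t in transcripts:
        frac[t] = (
            truth.loc[t, "true_m6a_pct_control"] / 100.0,
            truth.loc[t, "true_m6a_pct_case"] / 100.0,
        )
        total[t] = (1.0, float(truth.loc[t, "true_expr_ratio"]))
    frac["CTA850"] = (QPCR_POS_FRACTION, QPCR_POS_FRACTION)
    frac["CTA650"] = (QPCR_NEG_FRACTION, QPCR_NEG_FRACTION)
    total["CTA850"] = total["CTA650"] = (1.0, 1.0)

    groups = [(GROUP_CASE, "chol_q"), (GROUP_CONTROL, "skin_q")]
    n_rows = len(targets) * 2 * n_per_group * n_replicates * 2
    noise = _normals(cfg.seed, _STREAM_QPCR, n_rows) * sd
    rows = []
    i = 0
    for target in targets:
        for gi, (group, prefix) in enumerate(groups):
            case = group == GROUP_CASE
            f = frac[target][1 if case else 0]
            T = total[target][1 if case else 0]
            for s in range(n_per_group):
                sample_id = f"{prefix}{s + 1}"
                for rep in range(1, n_replicates + 1):
                    ct_ip = QPCR_CT_BASE - math.log2(f * T) + noise[i]
                    ct_in = (
                        QPCR_CT_BASE - math.log2(input_fraction * T) + noise[i + 1]
                    )
                    i += 2
                    rows.append((sample_id, group, target, "IP", rep, ct_ip))
                    rows.append((sample_id, group, target, "input", rep, ct_in))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "target_id", "role", "replicate", "ct"]
    )


def simulation_design(cfg: SimConfig, n_spike: int = 8) -> ArrayDesign:
    """Design sized to the configuration (study scale when unspecified)."""
    n = cfg.n_transcripts
    if n is None:
        return default_design(n_spike_pos=n_spike, n_spike_neg=n_spike)
    return default_design(n_mrna=n, n_spike_pos=n_spike, n_spike_neg=n_spike)
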