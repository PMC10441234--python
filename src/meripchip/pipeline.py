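"""End-to-end orchestration: normalize -> quantify -> QC -> differential
calls -> quadrant association -> clustering -> enrichment -> optional
MeRIP-qPCR, with every stage table written to the output directory and a
deterministic JSON summary.

Configuration is a flat YAML mapping (see :class:`RunConfig`); every CLI
flag overrides the file. Stage failures abort with a stage-named error.
The JSON summary and all stage tables are byte-identical across runs
with the same configuration and seed; wall-clock timestamps appear only
in the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .association import assign_quadrants, quadrant_counts, quadrant_plot_table
from .cluster import heatmap_matrix, hierarchical_cluster
from .containers import IntensityMatrix
from .design import read_design, write_design
from .differential import (
    ALPHA_DEFAULT,
    FC_HI_DEFAULT,
    FC_LO_DEFAULT,
    call_differential,
    direction_counts,
    volcano_table,
)
from .enrichment import fisher_enrichment, read_gmt, toy_gene_sets, write_gmt
from .errors import MeripChipError, StageError, ValidationError
from .qc import merip_spikein_qc, qc_summary
from .qpcr import compare_all_targets, control_normalize, validate_qpcr_table
from .quantify import quantify, write_quant_tsv
from .simulate import (
    SimConfig,
    simulate_experiment,
    simulate_qpcr,
    simulation_design,
    write_truth,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and options for one pipeline run."""

    design: str
    ip_raw: str
    sup_raw: str
    outdir: str
    gmt: str | None = None
    qpcr: str | None = None
    fc_hi: float = FC_HI_DEFAULT
    fc_lo: float = FC_LO_DEFAULT
    alpha: float = ALPHA_DEFAULT
    test: str = "welch"
    metric: str = "euclidean"
    linkage: str = "complete"
    enrichment_alternative: str = "greater"
    input_fraction: float = 0.1
    top_n_heatmap: int = 50
    spike_min_ratio: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fc_hi > 1.0 > self.fc_lo > 0.0):
            raise ValidationError("need fc_hi > 1 > fc_lo > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _Stages:
    """Stage runner that re-raises failures with the stage name."""

    def __init__(self, log_lines: list[str]):
        self.log_lines = log_lines

    def run(self, name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except MeripChipError as exc:
            raise StageError(name, exc) from exc
        except OSError as exc:
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        line = f"stage {name}: ok ({dt:.2f}s)"
        logger.info(line)
        self.log_lines.append(line)
        return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the JSON summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"meripchip {__version__}", f"config: {cfg.to_dict()}"]
    stages = _Stages(log_lines)
    manifest: list[str] = []

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    design = stages.run("load_design", lambda: read_design(cfg.design))
    ip_raw = stages.run("load_ip", lambda: IntensityMatrix.from_tsv(cfg.ip_raw))
    sup_raw = stages.run("load_sup", lambda: IntensityMatrix.from_tsv(cfg.sup_raw))

    quant = stages.run(
        "quantify", lambda: quantify(ip_raw, sup_raw, design)
    )
    save("m6a_quantity.tsv", lambda p: write_quant_tsv(quant.m6a_quantity, p))
    save("m6a_pct.tsv", lambda p: write_quant_tsv(quant.m6a_pct, p))
    save("expression.tsv", lambda p: write_quant_tsv(quant.expression, p))

    def spike_qc():
        pos = ip_raw.values.loc[design.spike_probe_ids("IP")].mean().mean()
        neg = ip_raw.values.loc[design.spike_probe_ids("Sup")].mean().mean()
        return merip_spikein_qc(float(pos), float(neg), cfg.spike_min_ratio)

    gate = stages.run("qc", spike_qc)
    qc_text, qc_record = qc_summary([gate])
    save("qc_summary.txt", lambda p: Path(p).write_text(qc_text))
    save("qc_summary.json", lambda p: _write_json(qc_record, Path(p)))

    def diff(kind, values):
        return call_differential(
            values,
            quant.groups,
            kind=kind,
            fc_hi=cfg.fc_hi,
            fc_lo=cfg.fc_lo,
            alpha=cfg.alpha,
            test=cfg.test,
        )

    meth = stages.run(
        "differential_methylation", lambda: diff("methylation", quant.m6a_quantity)
    )
    expr = stages.run(
        "differential_expression", lambda: diff("expression", quant.expression)
    )
    symbols = design.gene_symbol_of()
    for name, table in (("meth_diff.tsv", meth), ("expr_diff.tsv", expr)):
        out = table.copy()
        out.insert(0, "gene_symbol", symbols.reindex(out.index))
        save(name, lambda p, o=out: o.to_csv(p, sep="\t"))
    save(
        "meth_volcano.tsv", lambda p: volcano_table(meth).to_csv(p, sep="\t")
    )
    save(
        "expr_volcano.tsv", lambda p: volcano_table(expr).to_csv(p, sep="\t")
    )

    quad = stages.run("quadrant", lambda: assign_quadrants(meth, expr))
    counts = quadrant_counts(quad)
    save("quadrants.tsv", lambda p: quad.to_csv(p, sep="\t"))
    save("quadrant_summary.json", lambda p: _write_json(counts, Path(p)))
    save(
        "quadrant_plot.tsv",
        lambda p: quadrant_plot_table(quad, meth, expr).to_csv(p, sep="\t"),
    )

    def clustering():
        out = {}
        for tag, values, ptab in (
            ("meth", quant.m6a_quantity, meth),
            ("expr", quant.expression, expr),
        ):
            dendro = hierarchical_cluster(
                values, axis="samples", metric=cfg.metric, method=cfg.linkage
            )
            save(
                f"dendrogram_{tag}_samples.nwk",
                lambda p, d=dendro: Path(p).write_text(d.to_newick() + "\n"),
            )
            hm = heatmap_matrix(
                values,
                ptab["p_value"],
                min(cfg.top_n_heatmap, len(values)),
                metric=cfg.metric,
                method=cfg.linkage,
            )
            save(f"heatmap_{tag}.tsv", lambda p, h=hm: h.to_csv(p, sep="\t"))
            out[tag] = dendro
        return out

    stages.run("clustering", clustering)

    enrich_summary = {}
    if cfg.gmt is not None:
        def enrich():
            sets = read_gmt(cfg.gmt)
            universe = set(design.mrna["gene_symbol"])
            for label, table in (("hyper", meth), ("hypo", meth)):
                direction = table["direction"] == label
                query = set(
                    symbols.reindex(table.index[direction]).dropna()
                )
                res = fisher_enrichment(
                    query, sets, universe, alternative=cfg.enrichment_alternative,
                    alpha=cfg.alpha,
                )
                save(
                    f"enrichment_{label}.tsv",
                    lambda p, r=res: r.to_csv(p, sep="\t", index=False),
                )
                enrich_summary[f"n_significant_sets_{label}"] = int(
                    res["significant"].sum()
                ) if len(res) else 0

        stages.run("enrichment", enrich)

    qpcr_summary = {}
    if cfg.qpcr is not None:
        def qpcr_stage():
            import pandas as pd

            table = validate_qpcr_table(pd.read_csv(cfg.qpcr, sep="\t"))
            norm = control_normalize(
                table, input_fraction=cfg.input_fraction,
                min_ratio=cfg.spike_min_ratio,
            )
            comps = compare_all_targets(norm)
            save("qpcr_normalized.tsv", lambda p: norm.to_csv(p, sep="\t", index=False))
            save(
                "qpcr_comparisons.tsv",
                lambda p: comps.to_csv(p, sep="\t", index=False),
            )
            qpcr_summary["n_qpcr_targets"] = int(len(comps))
            qpcr_summary["n_qpcr_significant"] = int(
                (comps["p_value"] < cfg.alpha).sum()
            )

        stages.run("qpcr", qpcr_stage)

    meth_counts = direction_counts(meth)
    expr_counts = direction_counts(expr)
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "n_transcripts": int(len(quant.m6a_quantity)),
        "n_hyper": meth_counts.get("hyper", 0),
        "n_hypo": meth_counts.get("hypo", 0),
        "n_up": expr_counts.get("up", 0),
        "n_down": expr_counts.get("down", 0),
        "hyper_up": counts["hyper_up"],
        "hyper_down": counts["hyper_down"],
        "hypo_up": counts["hypo_up"],
        "hypo_down": counts["hypo_down"],
        "unassigned": counts["unassigned"],
        "qc": qc_record,
        **enrich_summary,
        **qpcr_summary,
    }
    _write_json(summary, outdir / "summary.json")
    manifest.append("summary.json")
    _write_json({"outputs": manifest}, outdir / "manifest.json")
    log_lines.append(f"wrote {len(manifest)} outputs to {outdir}")
    (outdir / "run_log.txt").write_text(
        "\n".join(log_lines + [f"finished at {time.strftime('%Y-%m-%dT%H:%M:%S')}"])
        + "\n"
    )
    return summary


def simulate_command(
    outdir,
    cfg: SimConfig,
    n_spike: int = 8,
    with_qpcr: bool = True,
    with_gmt: bool = True,
) -> dict:
    """Write a complete simulated fixture directory.

    Emits the design, both raw channel TSVs, the truth table, a toy GMT,
    an optional qPCR Ct table for the validated transcripts present in
    the design, and a manifest echoing the seed and configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = simulation_design(cfg, n_spike=n_spike)
    ip, sup, truth = simulate_experiment(design, cfg)
    write_design(design, outdir / "design.tsv")
    ip.to_tsv(outdir / "ip_raw.tsv")
    sup.to_tsv(outdir / "sup_raw.tsv")
    write_truth(truth, outdir / "truth.tsv")
    files = ["design.tsv", "ip_raw.tsv", "sup_raw.tsv", "truth.tsv"]
    if with_gmt:
        write_gmt(toy_gene_sets(design), outdir / "toy_sets.gmt")
        files.append("toy_sets.gmt")
    if with_qpcr:
        from .design import VALIDATED_TRANSCRIPTS

        targets = [
            t for t, _ in VALIDATED_TRANSCRIPTS if t in truth.index
        ] or list(truth.index[: min(3, len(truth))])
        qpcr = simulate_qpcr(truth, targets, cfg)
        qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
        files.append("qpcr.tsv")
    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "outputs": files,
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
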