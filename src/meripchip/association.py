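"""Four-quadrant association of methylation and expression calls.

Transcripts called on both axes fall into one of four quadrants
(hyper_up, hyper_down, hypo_up, hypo_down); all others are retained as
``unassigned`` so the partition conserves the transcript universe. The
empty quadrants are reported explicitly with count 0 — the study
specifically notes the absence of hypomethylated-upregulated mRNAs.
"""

from __future__ import annotations

import pandas as pd

from .errors import AlignmentError, ValidationError

QUADRANTS = ("hyper_up", "hyper_down", "hypo_up", "hypo_down")

_QUADRANT_OF = {
    ("hyper", "up"): "hyper_up",
    ("hyper", "down"): "hyper_down",
    ("hypo", "up"): "hypo_up",
    ("hypo", "down"): "hypo_down",
}

#: Figure-legend colors; hypo_up was absent in the study so it carries a
#: color beyond the published legend.
QUADRANT_COLORS = {
    "hyper_up": "red",
    "hyper_down": "green",
    "hypo_down": "blue",
    "hypo_up": "orange",
}


def assign_quadrants(meth: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Cross-classify aligned methylation and expression call tables.

    Both inputs are ``call_differential`` outputs over the same
    transcript universe; a mismatch raises an alignment error listing
    the offending ids.
    """
    only_meth = meth.index.difference(expr.index)
    only_expr = expr.index.difference(meth.index)
    if len(only_meth) or len(only_expr):
        raise AlignmentError(
            "transcript universes differ; "
            f"only in methylation table: {list(only_meth[:5])}, "
            f"only in expression table: {list(only_expr[:5])}"
        )
    expr = expr.loc[meth.index]
    quadrant = [
        _QUADRANT_OF.get((m, e), "unassigned")
        for m, e in zip(meth["direction"], expr["direction"])
    ]
    out = pd.DataFrame(
        {
            "meth_direction": meth["direction"],
            "expr_direction": expr["direction"].to_numpy(),
            "quadrant": quadrant,
        },
        index=meth.index,
    )
    out.index.name = "transcript_id"
    return out


def quadrant_counts(quad: pd.DataFrame) -> dict[str, int]:
    """Counts for all four quadrants (zeros included) plus unassigned."""
    vc = quad["quadrant"].value_counts()
    counts = {q: int(vc.get(q, 0)) for q in QUADRANTS}
    counts["unassigned"] = int(vc.get("unassigned", 0))
    return counts


def quadrant_plot_table(
    quad: pd.DataFrame, meth: pd.DataFrame, expr: pd.DataFrame
) -> pd.DataFrame:
    """Plot-ready table for the four-quadrant diagram.

    One row per transcript significant on both axes, with both log2 fold
    changes and the legend color.
    """
    for name, table in (("methylation", meth), ("expression", expr)):
        if not quad.index.equals(table.index):
            missing = quad.index.difference(table.index)
            raise AlignmentError(
                f"{name} table not aligned with quadrant table "
                f"(e.g. {list(missing[:5])})"
            )
    keep = quad["quadrant"] != "unassigned"
    out = pd.DataFrame(
        {
            "log2_meth_fc": meth.loc[keep, "log2fc"],
            "log2_expr_fc": expr.loc[keep, "log2fc"],
            "quadrant": quad.loc[keep, "quadrant"],
        }
    )
    out["color"] = [QUADRANT_COLORS[q] for q in out["quadrant"]]
    out.index.name = "transcript_id"
    return out


def check_universe(quad: pd.DataFrame, n_universe: int) -> None:
    """Conservation check: quadrant counts plus unassigned = universe."""
    counts = quadrant_counts(quad)
    if sum(counts.values()) != n_universe:
        raise ValidationError(
            f"quadrant partition covers {sum(counts.values())} transcripts, "
            f"expected {n_universe}"
        )
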