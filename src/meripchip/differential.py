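"""Between-group differential calling on log2 quantities.

The study calls a transcript differentially m6A-modified (or expressed)
when the linear fold change between groups reaches 3 in either direction
and the p-value is below 0.05: FC >= 3 ("hyper"/"up"), FC <= 1/3
("hypo"/"down"), both with p < 0.05. Fold change is the ratio of
geometric means, 2^(mean2 - mean1), with group 2 the cholesteatoma
(case) group and group 1 the skin (control) group by convention.

The study does not name its test; the default here is Welch's
unequal-variance two-sample t-test on the log2 values (Student's is
available via ``test="student"``). Raw p-values are filtered, matching
the study; Benjamini-Hochberg q-values can be reported alongside with
``adjust=True`` but never drive the direction call.

Degenerate inputs (both groups with zero variance) get p = 1 when the
means are equal (no evidence of a difference) and p = 0 otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GROUP_CASE, GROUP_CONTROL
from .errors import ValidationError

FC_HI_DEFAULT = 3.0
FC_LO_DEFAULT = 1.0 / 3.0
ALPHA_DEFAULT = 0.05
NEG_LOG10_P_CAP = 320.0

DIRECTION_LABELS = {
    "methylation": ("hyper", "hypo"),
    "expression": ("up", "down"),
}


def fold_change(values_group1, values_group2) -> float:
    """Linear group2/group1 ratio of geometric means on log2 inputs."""
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("fold_change requires nonempty groups")
    return float(np.exp2(g2.mean() - g1.mean()))


def welch_p(values_group1, values_group2, test: str = "welch") -> float:
    """Two-sided two-sample t-test p-value on log2 values.

    ``test`` is "welch" (unequal variances, default) or "student".
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if test not in ("welch", "student"):
        raise ValidationError("test must be 'welch' or 'student'")
    if g1.var(ddof=1) == 0.0 and g2.var(ddof=1) == 0.0:
        return 1.0 if g1.mean() == g2.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(g2, g1, equal_var=(test == "student"))
    return float(res.pvalue)


def classify_direction(
    fc: float,
    p: float,
    fc_hi: float = FC_HI_DEFAULT,
    fc_lo: float = FC_LO_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    labels: tuple[str, str] = ("hyper", "hypo"),
) -> str:
    """Apply the calling rule to one (fold change, p) pair.

    Thresholds are inclusive on fold change (>= fc_hi, <= fc_lo) and
    strict on p (< alpha), as stated by the protocol.
    """
    if p < alpha:
        if fc >= fc_hi:
            return labels[0]
        if fc <= fc_lo:
            return labels[1]
    return "none"


def call_differential(
    values: pd.DataFrame,
    groups: dict[str, str],
    kind: str = "methylation",
    fc_hi: float = FC_HI_DEFAULT,
    fc_lo: float = FC_LO_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    test: str = "welch",
    adjust: bool = False,
    group1: str | None = None,
    group2: str | None = None,
) -> pd.DataFrame:
    """Call every transcript in a log2 transcripts x samples matrix.

    Returns a DataFrame indexed by transcript with columns
    mean_log2_group1, mean_log2_group2, log2fc, fold_change, p_value,
    direction (and q_bh when ``adjust``). Direction labels follow
    ``kind``: hyper/hypo for methylation, up/down for expression.
    """
    if kind not in DIRECTION_LABELS:
        raise ValidationError(f"kind must be one of {sorted(DIRECTION_LABELS)}")
    if not (fc_hi > 1.0 > fc_lo > 0.0):
        raise ValidationError("need fc_hi > 1 > fc_lo > 0")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    group1, group2 = _resolve_groups(values.columns, groups, group1, group2)
    cols1 = [s for s in values.columns if groups[s] == group1]
    cols2 = [s for s in values.columns if groups[s] == group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValidationError("each group needs at least 2 samples")
    a1 = values[cols1].to_numpy(dtype=float)
    a2 = values[cols2].to_numpy(dtype=float)
    m1 = a1.mean(axis=1)
    m2 = a2.mean(axis=1)
    log2fc = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a2, a1, axis=1, equal_var=(test == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a1.var(axis=1, ddof=1) == 0.0) & (a2.var(axis=1, ddof=1) == 0.0)
    p[degenerate] = np.where(m1[degenerate] == m2[degenerate], 1.0, 0.0)
    fc = np.exp2(log2fc)
    labels = DIRECTION_LABELS[kind]
    direction = np.full(len(values), "none", dtype=object)
    called = p < alpha
    direction[called & (fc >= fc_hi)] = labels[0]
    direction[called & (fc <= fc_lo)] = labels[1]
    out = pd.DataFrame(
        {
            "mean_log2_group1": m1,
            "mean_log2_group2": m2,
            "log2fc": log2fc,
            "fold_change": fc,
            "p_value": p,
            "direction": direction,
        },
        index=values.index,
    )
    out.index.name = "transcript_id"
    if adjust:
        from statsmodels.stats.multitest import multipletests

        out["q_bh"] = multipletests(p, method="fdr_bh")[1]
    return out


def _resolve_groups(columns, groups, group1, group2) -> tuple[str, str]:
    present = {groups[s] for s in columns}
    if group1 is None and group2 is None:
        if present == {GROUP_CONTROL, GROUP_CASE}:
            return GROUP_CONTROL, GROUP_CASE
        if len(present) == 2:
            return tuple(sorted(present))  # type: ignore[return-value]
        raise ValidationError(f"expected exactly 2 groups, found {sorted(present)}")
    if group1 is None or group2 is None:
        raise ValidationError("give both group1 and group2 or neither")
    for g in (group1, group2):
        if g not in present:
            raise ValidationError(f"group {g!r} not present in the matrix")
    return group1, group2


def direction_counts(diff: pd.DataFrame) -> dict[str, int]:
    counts = diff["direction"].value_counts().to_dict()
    return {str(k): int(v) for k, v in counts.items()}


def volcano_table(diff: pd.DataFrame, cap: float = NEG_LOG10_P_CAP) -> pd.DataFrame:
    """Plot-ready volcano columns; p = 0 maps to the configured cap.

    Direction tallies are attached as ``df.attrs["direction_counts"]``.
    """
    p = diff["p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        nlp = np.where(p > 0, -np.log10(p), np.inf)
    out = pd.DataFrame(
        {
            "log2fc": diff["log2fc"],
            "neg_log10_p": np.minimum(nlp, cap),
            "direction": diff["direction"],
        },
        index=diff.index,
    )
    out.attrs["direction_counts"] = direction_counts(diff)
    return out
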