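"""Agglomerative hierarchical clustering for heatmap ordering.

Samples (and transcripts) are clustered on normalized log2 quantities
with Euclidean distance and complete linkage by default — the common
heatmap defaults; both are configurable. Merge heights of the monotone
linkages (complete, average, single) are nondecreasing. Dendrograms
serialize to Newick with merge-height differences as branch lengths.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ValidationError


@dataclasses.dataclass(eq=False)
class DendrogramSpec:
    """One axis' agglomeration: ids, scipy linkage matrix, leaf order."""

    ids: list[str]
    linkage_matrix: np.ndarray
    metric: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, k: int) -> dict[str, int]:
        """Partition the items into k flat clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "samples",
    metric: str = "euclidean",
    method: str = "complete",
) -> DendrogramSpec:
    """Cluster one axis of a transcripts x samples log2 matrix.

    ``axis="samples"`` clusters the columns, ``axis="transcripts"`` the
    rows. Input must be free of missing values; results are
    deterministic for a fixed input order.
    """
    if axis == "samples":
        X = matrix.to_numpy(dtype=float).T
        ids = [str(c) for c in matrix.columns]
    elif axis == "transcripts":
        X = matrix.to_numpy(dtype=float)
        ids = [str(i) for i in matrix.index]
    else:
        raise ValidationError("axis must be 'samples' or 'transcripts'")
    if len(ids) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if not np.isfinite(X).all():
        raise ValidationError("matrix contains missing or non-finite values")
    Z = hierarchy.linkage(X, method=method, metric=metric)
    return DendrogramSpec(ids=ids, linkage_matrix=Z, metric=metric, method=method)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores (ddof=1); constant rows map to all zeros."""
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def heatmap_matrix(
    values: pd.DataFrame,
    p_values: pd.Series,
    top_n: int,
    metric: str = "euclidean",
    method: str = "complete",
    dendro_samples: DendrogramSpec | None = None,
    dendro_transcripts: DendrogramSpec | None = None,
) -> pd.DataFrame:
    """Plot-ready heatmap block: top transcripts, z-scored and ordered.

    Rows are the ``top_n`` transcripts by ascending p-value (stable
    tie-break on input order), z-scored per row, then ordered by the
    transcript dendrogram's leaf order; columns follow the sample
    dendrogram. Dendrograms are computed on the z-scored block when not
    supplied.
    """
    if top_n < 1:
        raise ValidationError("top_n must be at least 1")
    if top_n > len(values):
        raise ValidationError(
            f"top_n={top_n} exceeds transcript count {len(values)}"
        )
    p = p_values.reindex(values.index)
    if p.isna().any():
        raise ValidationError("p_values missing for some transcripts")
    top = p.sort_values(kind="stable").index[:top_n]
    z = zscore_rows(values.loc[top])
    if dendro_transcripts is None:
        if len(z) >= 2:
            dendro_transcripts = hierarchical_cluster(
                z, axis="transcripts", metric=metric, method=method
            )
    if dendro_samples is None:
        dendro_samples = hierarchical_cluster(
            z, axis="samples", metric=metric, method=method
        )
    row_order = (
        [t for t in dendro_transcripts.leaf_order if t in z.index]
        if dendro_transcripts is not None
        else list(z.index)
    )
    col_order = [s for s in dendro_samples.leaf_order if s in z.columns]
    return z.loc[row_order, col_order]
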