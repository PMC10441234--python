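"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route disjoint from the package's
implementation path: exact integer enumeration for the hypergeometric
tail, the textbook Welch formula, nested-loop set intersection for
quadrant counts, and a naive O(n^3) agglomerative merger for clustering.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), X ~ Hypergeometric(N, K, n), by exact integer summation."""
    denom = math.comb(N, n)
    num = 0
    for i in range(max(k, 0, n - (N - K)), min(K, n) + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return num / denom


def welch_p_oracle(g1, g2) -> float:
    """Two-sided Welch t-test from the textbook statistic and t CDF."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    n1, n2 = len(g1), len(g2)
    v1 = g1.var(ddof=1)
    v2 = g2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (g2.mean() - g1.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def quadrant_counts_bruteforce(meth_dir: dict, expr_dir: dict) -> dict:
    """Nested-loop intersection of two direction mappings."""
    counts = {
        "hyper_up": 0,
        "hyper_down": 0,
        "hypo_up": 0,
        "hypo_down": 0,
        "unassigned": 0,
    }
    for t in meth_dir:
        m = meth_dir[t]
        e = expr_dir[t]
        matched = False
        for mm in ("hyper", "hypo"):
            for ee in ("up", "down"):
                if m == mm and e == ee:
                    counts[f"{mm}_{ee}"] += 1
                    matched = True
        if not matched:
            counts["unassigned"] += 1
    return counts


def complete_linkage_bruteforce(X: np.ndarray):
    """Naive agglomerative complete linkage on Euclidean distances.

    Returns (merge_heights, cophenetic) where cophenetic[i, j] is the
    height at which observations i and j first share a cluster.
    """
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters: list[set[int]] = [{i} for i in range(n)]
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return np.array(heights), coph
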