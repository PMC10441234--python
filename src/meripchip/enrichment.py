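"""Gene-set over-representation by Fisher's exact test.

Query genes (e.g. symbols of hypermethylated transcripts) are tested
against user-supplied GMT gene sets over a background universe that
defaults, in the pipeline, to all mRNA gene symbols on the array rather
than the genome. Significance is the one-sided hypergeometric tail

    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n)

(over-representation; the two-sided variant is available), reported with
the enrichment score -log10(p) and a significance flag at p < 0.05.
Benjamini-Hochberg q-values are reported alongside but do not drive the
flag, matching the raw-p thresholding of the source protocol.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
SCORE_CAP = 320.0


@dataclasses.dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.set_id!r} has duplicates")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: ``set_id<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are dropped with a logged warning;
    an empty file yields an empty collection.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, found {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s:%d: duplicate gene %r in set %r dropped",
                        path, lineno, g, set_id,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets.append(GeneSet(set_id, description, tuple(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join((s.set_id, s.description) + s.genes) + "\n")


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_score(p_value: float) -> float:
    """-log10(p) for p in (0, 1]."""
    if not (0.0 < p_value <= 1.0):
        raise ValidationError("p-value must be in (0, 1]")
    return max(0.0, -math.log10(p_value))


def fisher_enrichment(
    query,
    sets: list[GeneSet],
    universe,
    alternative: str = "greater",
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Test every gene set for over-representation of the query.

    Set members are intersected with the universe before testing; sets
    with no members left are skipped with a warning. Records are sorted
    by ascending p-value.
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValidationError(
            f"query genes outside the universe: {offenders[:10]}"
        )
    if alternative not in ("greater", "two-sided"):
        raise ValidationError("alternative must be 'greater' or 'two-sided'")
    N = len(universe)
    n = len(query)
    rows = []
    for s in sets:
        members = set(s.genes) & universe
        K = len(members)
        if K == 0:
            logger.warning(
                "gene set %r has no members in the universe; skipped", s.set_id
            )
            continue
        k = len(query & members)
        if alternative == "greater":
            p = hypergeom_sf(k, N, K, n)
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        p = min(max(p, 0.0), 1.0)
        score = enrichment_score(p) if p > 0 else SCORE_CAP
        rows.append(
            {
                "set_id": s.set_id,
                "description": s.description,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "score": min(score, SCORE_CAP),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_id", "description", "k", "K", "n", "N", "p_value", "score"],
    )
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_value"] < alpha
        out = out.sort_values(
            ["p_value", "set_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        out["q_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def toy_gene_sets(design) -> list[GeneSet]:
    """Two deterministic toy sets over a design's mRNA gene symbols.

    A "keratinization-like" set drawn from the front of the manifest
    (where simulations plant hypermethylation) and a "Hippo-like" set
    spread over the back half, so hermetic tests can observe both an
    enriched and a background set.
    """
    symbols = list(design.mrna["gene_symbol"])
    n = len(symbols)
    front = symbols[: min(50, max(3, n // 4))]
    step = max(1, (n - n // 2) // 50)
    back = symbols[n // 2 :: step][:50]
    if len(back) < 3:
        back = symbols[-3:]
    sets = [
        GeneSet("KERATINIZATION_LIKE", "toy keratinization-like set", tuple(front)),
        GeneSet("HIPPO_LIKE", "toy Hippo-like set", tuple(back)),
    ]
    return sets
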