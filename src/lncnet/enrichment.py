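"""Gene-set over-representation analysis (ORA).

Given a query gene list (e.g. the upregulated DE mRNAs in the coexpression
network), a background universe (all genes on the array by default) and a
GMT collection, each set is scored with the hypergeometric upper tail
P[X >= k] for the observed overlap k, with Benjamini-Hochberg FDR across
sets. Significance is flagged at raw P < 0.05 in keeping with the legacy
screening convention; the FDR column is always reported.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSet

DEFAULT_ENRICH_P = 0.05

RESULT_COLUMNS = [
    "set_id",
    "description",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "fdr",
    "significant",
    "overlap",
]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    gene_sets: Sequence[GeneSet],
    p_threshold: float = DEFAULT_ENRICH_P,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set against ``universe``.

    Query genes outside the universe are dropped with a warning; set members
    are likewise restricted to the universe before counting. Results are
    sorted by p_value (ties by set_id) with a ``significant`` flag at raw
    p < p_threshold.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) not in universe dropped: "
            f"{sorted(stray)[:5]}",
            stacklevel=2,
        )
        query &= universe
    if not query:
        warnings.warn("empty query after universe intersection", stacklevel=2)
        return pd.DataFrame(columns=RESULT_COLUMNS)

    N, n = len(universe), len(query)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        K = len(members)
        overlap = sorted(members & query)
        k = len(overlap)
        p = hypergeom_upper_tail(k, N, K, n) if K else 1.0
        rows.append((gs.set_id, gs.description, k, K, n, N, p, overlap))
    out = pd.DataFrame(
        rows,
        columns=["set_id", "description", "k", "K", "n", "N", "p_value", "overlap"],
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    out["significant"] = out["p_value"] < p_threshold
    out["overlap"] = out["overlap"].map(lambda genes: ";".join(genes))
    out = out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(
        drop=True
    )
    return out[RESULT_COLUMNS]


def split_by_direction(
    de_results: pd.DataFrame,
    symbols: Mapping[str, str] | None = None,
    biotype: str | None = None,
) -> tuple[list[str], list[str]]:
    """Partition DE probes into (upregulated, downregulated) gene lists.

    Keys on the sign of log2fc among ``is_de`` probes (zero log2fc cannot be
    DE because of the fold-change gate, asserted). ``symbols`` maps probe id
    to gene symbol when the annotation provides one; otherwise probe ids are
    used. ``biotype`` optionally restricts to one biotype.
    """
    de = de_results[de_results["is_de"]]
    if biotype is not None:
        de = de[de["biotype"] == biotype]
    assert not (de["log2fc"] == 0).any(), "DE probe with zero log2fc"
    ident = (lambda p: symbols.get(p, p)) if symbols is not None else (lambda p: p)
    up = [ident(p) for p in de.index[de["log2fc"] > 0]]
    down = [ident(p) for p in de.index[de["log2fc"] < 0]]
    return up, down
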