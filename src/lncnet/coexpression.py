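"""Coding-noncoding coexpression (CNC) network construction.

Edges link a differentially expressed lncRNA to a differentially expressed
mRNA whose expression profiles correlate strongly across samples: Pearson
|r| > 0.7 with a two-sided correlation-test P < 0.05 (both strict, matching
the screening convention of this kind of array study). Correlations are
computed over all samples pooled by default — the usual CNC practice, which
maximises n — with a within-group option. Hubs are nodes with raw degree
strictly greater than 60, and the strongest links are the top edges ranked
by ascending P.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LNCRNA, MRNA, ExpressionMatrix, ValidationError
from .diffexpr import DesignError

log = logging.getLogger(__name__)

DEFAULT_PCC_THRESHOLD = 0.7
DEFAULT_EDGE_P_THRESHOLD = 0.05
DEFAULT_MIN_DEGREE = 60
DEFAULT_TOP_K = 30

EDGE_COLUMNS = ["lnc_id", "mrna_id", "pcc", "p_value", "fdr", "n"]


def correlation_p(r, n: int):
    """Two-sided P for a Pearson correlation r at sample size n.

    Uses the exact null relation t = r * sqrt(n-2) / sqrt(1-r^2) on n-2
    degrees of freedom; |r| = 1 maps to P = 0. Accepts scalars or arrays.
    """
    if n < 4:
        raise DesignError(f"correlation test needs n >= 4 samples, got {n}")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValidationError("correlation outside [-1, 1]")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt(n - 2) / np.sqrt(1.0 - r_arr**2)
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return float(p) if np.isscalar(r) or p.ndim == 0 else p


@dataclass
class CNCNetwork:
    """Bipartite lncRNA-mRNA coexpression network.

    ``edges``: DataFrame with columns lnc_id, mrna_id, pcc, p_value, fdr, n.
    ``nodes``: DataFrame indexed by node id with biotype, direction (+1/-1
    from the DE sign), degree.
    """

    edges: pd.DataFrame
    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.edges.duplicated(subset=["lnc_id", "mrna_id"]).any():
            raise ValidationError("duplicate edges in CNC network")
        lnc = set(self.edges["lnc_id"])
        mrna = set(self.edges["mrna_id"])
        if lnc & mrna:
            raise ValidationError("network is not bipartite")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node_id: str) -> int:
        return int(self.nodes.loc[node_id, "degree"])

    def to_graph(self) -> nx.Graph:
        """Materialise as a networkx bipartite graph with node/edge attributes."""
        g = nx.Graph()
        for node_id, row in self.nodes.iterrows():
            g.add_node(
                node_id,
                biotype=row["biotype"],
                direction=int(row["direction"]),
                degree=int(row["degree"]),
                bipartite=0 if row["biotype"] == LNCRNA else 1,
            )
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.lnc_id, row.mrna_id, pcc=float(row.pcc), p=float(row.p_value))
        return g


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations between two matrices over columns."""
    n = x.shape[1]
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    ys = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, ddof=1, keepdims=True)
    r = xs @ ys.T / (n - 1)
    return np.clip(r, -1.0, 1.0)


def build_cnc(
    matrix: ExpressionMatrix,
    de_results: pd.DataFrame,
    *,
    pcc_threshold: float = DEFAULT_PCC_THRESHOLD,
    p_threshold: float = DEFAULT_EDGE_P_THRESHOLD,
    samples: str = "pooled",
) -> CNCNetwork:
    """Build the CNC network over all DE-lncRNA x DE-mRNA pairs.

    ``samples`` selects the correlation sample set: ``"pooled"`` (all
    samples, default), ``"case"`` or ``"control"``. Edges satisfy
    |pcc| > pcc_threshold and p < p_threshold (strict). The ``fdr`` column is
    Benjamini-Hochberg over ALL candidate pairs, reported for modern use;
    probes with zero variance are skipped with a warning. Nodes without a
    surviving edge are not part of the network.
    """
    de = de_results[de_results["is_de"]]
    lnc_ids = [p for p in de.index if de.loc[p, "biotype"] == LNCRNA]
    mrna_ids = [p for p in de.index if de.loc[p, "biotype"] == MRNA]
    if not lnc_ids or not mrna_ids:
        raise ValidationError("need at least one DE lncRNA and one DE mRNA")

    if samples == "pooled":
        cols = matrix.sample_ids
    elif samples == "case":
        cols = matrix.case_ids
    elif samples == "control":
        cols = matrix.control_ids
    else:
        raise ValueError(f"samples must be 'pooled', 'case' or 'control', got {samples!r}")
    n = len(cols)
    if n < 4:
        raise DesignError(f"correlation needs >= 4 samples, got {n}")

    x = matrix.values.loc[lnc_ids, cols].to_numpy(float)
    y = matrix.values.loc[mrna_ids, cols].to_numpy(float)
    x_ok = x.std(axis=1, ddof=1) > 0
    y_ok = y.std(axis=1, ddof=1) > 0
    if not x_ok.all() or not y_ok.all():
        skipped = [p for p, ok in zip(lnc_ids, x_ok) if not ok]
        skipped += [p for p, ok in zip(mrna_ids, y_ok) if not ok]
        warnings.warn(
            f"skipping {len(skipped)} zero-variance probe(s): {skipped[:5]}",
            stacklevel=2,
        )
        log.warning("zero-variance probes skipped: %s", skipped)
    lnc_ids = [p for p, ok in zip(lnc_ids, x_ok) if ok]
    mrna_ids = [p for p, ok in zip(mrna_ids, y_ok) if ok]
    x, y = x[x_ok], y[y_ok]

    r = _pearson_matrix(x, y)
    p = correlation_p(r, n)
    fdr = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    keep = (np.abs(r) > pcc_threshold) & (p < p_threshold)
    li, mi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "lnc_id": np.asarray(lnc_ids, dtype=object)[li],
            "mrna_id": np.asarray(mrna_ids, dtype=object)[mi],
            "pcc": r[li, mi],
            "p_value": p[li, mi],
            "fdr": fdr[li, mi],
            "n": n,
        },
        columns=EDGE_COLUMNS,
    )
    nodes = _node_table(edges, de_results)
    return CNCNetwork(edges=edges, nodes=nodes)


def _node_table(edges: pd.DataFrame, de_results: pd.DataFrame) -> pd.DataFrame:
    deg_lnc = edges["lnc_id"].value_counts()
    deg_mrna = edges["mrna_id"].value_counts()
    rows = []
    for node_id, deg in deg_lnc.items():
        rows.append((node_id, LNCRNA, deg))
    for node_id, deg in deg_mrna.items():
        rows.append((node_id, MRNA, deg))
    nodes = pd.DataFrame(rows, columns=["id", "biotype", "degree"]).set_index("id")
    direction = np.sign(de_results["log2fc"]).astype(int)
    nodes["direction"] = direction.reindex(nodes.index).fillna(0).astype(int)
    return nodes[["biotype", "direction", "degree"]].sort_index()


def degree_filter(
    network: CNCNetwork, min_degree: int = DEFAULT_MIN_DEGREE
) -> pd.DataFrame:
    """Hub nodes: degree strictly greater than ``min_degree``.

    Returns the node-table rows of the hubs (may be empty), so callers can
    partition by biotype.
    """
    return network.nodes[network.nodes["degree"] > min_degree].copy()


def top_edges(network: CNCNetwork, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """The k strongest edges, ascending P; ties by |pcc| descending, then ids.

    Returns all edges when the network has fewer than k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    edges = network.edges.copy()
    edges["_abs_pcc"] = edges["pcc"].abs()
    ranked = edges.sort_values(
        by=["p_value", "_abs_pcc", "lnc_id", "mrna_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_abs_pcc")
    return ranked.head(k).reset_index(drop=True)
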