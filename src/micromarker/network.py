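"""Thresholded Spearman co-occurrence networks.

Edges connect genus pairs (or genus/cell-type pairs across two matrices)
whose Spearman correlation exceeds a magnitude threshold with raw
p < alpha — the convention of microbiome co-occurrence figures; no
multiple-testing correction is applied by default, though a BH flag is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diff_abundance import bh_adjust

logger = logging.getLogger(__name__)

R_MIN = 0.3
ALPHA = 0.05

EDGE_COLUMNS = ["node_a", "node_b", "rho", "p", "sign"]


def spearman_edges(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame | None = None,
    r_min: float = R_MIN,
    alpha: float = ALPHA,
    bh: bool = False,
) -> pd.DataFrame:
    """Pairwise Spearman edges passing |rho| > r_min and p < alpha.

    Within-matrix mode (``matrix_b is None``) excludes self pairs and
    duplicates; cross-matrix mode correlates every column of A with every
    column of B (samples aligned by index). Constant columns have
    undefined rank correlation and are skipped with a warning. With
    ``bh=True`` the p filter applies to BH-adjusted p-values instead.
    """
    self_mode = matrix_b is None
    b_mat = matrix_a if self_mode else matrix_b
    if not matrix_a.index.equals(b_mat.index):
        raise ValueError("sample ids of the two matrices are not aligned")
    if len(matrix_a) < 4:
        raise ValueError("at least 4 samples required for edge testing")

    const_a = matrix_a.columns[matrix_a.nunique() <= 1]
    const_b = b_mat.columns[b_mat.nunique() <= 1]
    if len(const_a) or len(const_b):
        logger.warning(
            "skipping constant columns (rho undefined): %s",
            sorted(set(const_a) | set(const_b)),
        )
    a = matrix_a.drop(columns=const_a)
    b = b_mat.drop(columns=const_b)

    rows = []
    if self_mode:
        cols = list(a.columns)
        if len(cols) == 2:  # spearmanr returns a scalar for two columns
            r, pv = stats.spearmanr(a[cols[0]], a[cols[1]])
            rows.append((cols[0], cols[1], r, pv))
        elif len(cols) > 2:
            rho, p = stats.spearmanr(a.to_numpy())
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    rows.append((cols[i], cols[j], rho[i, j], p[i, j]))
    else:
        for ca in a.columns:
            for cb in b.columns:
                r, pv = stats.spearmanr(a[ca], b[cb])
                rows.append((ca, cb, r, pv))

    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p"])
    if bh and len(edges):
        edges["p"] = bh_adjust(edges["p"])
    edges = edges[(edges["rho"].abs() > r_min) & (edges["p"] < alpha)].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    return edges.reset_index(drop=True)[EDGE_COLUMNS]


def top_abundance_subnetwork(
    relabund: pd.DataFrame, k: int = 150, r_min: float = R_MIN, alpha: float = ALPHA
) -> tuple[pd.DataFrame, list[str]]:
    """Edge list restricted to the k genera of highest mean abundance."""
    if k > relabund.shape[1]:
        raise ValueError(f"k={k} exceeds genus count {relabund.shape[1]}")
    top = list(relabund.mean(axis=0).sort_values(ascending=False).index[:k])
    if k < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS), top
    return spearman_edges(relabund[top], r_min=r_min, alpha=alpha), top


@dataclass
class NetworkSummary:
    degrees: pd.Series
    n_edges: int
    n_positive: int
    n_negative: int
    n_components: int


def degrees(edges: pd.DataFrame, nodes=None) -> NetworkSummary:
    """Node degrees and component counts of a thresholded edge list."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for _, row in edges.iterrows():
        g.add_edge(row["node_a"], row["node_b"])
    deg = pd.Series(dict(g.degree()), dtype=int).sort_index()
    return NetworkSummary(
        degrees=deg,
        n_edges=g.number_of_edges(),
        n_positive=int((edges["sign"] == "positive").sum()) if len(edges) else 0,
        n_negative=int((edges["sign"] == "negative").sum()) if len(edges) else 0,
        n_components=nx.number_connected_components(g) if g.number_of_nodes() else 0,
    )
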