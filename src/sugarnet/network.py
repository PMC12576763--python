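"""Thresholded Pearson co-expression graph and basic topology.

Edges connect gene pairs with |Pearson r| strictly above the threshold
(default 0.90). The signed correlation is stored on each edge; consumers
choose |r| or sign-aware views. Genes isolated after thresholding are dropped
by default so the node count means "connected genes".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx


class ZeroVarianceError(ValueError):
    """A zero-variance gene reached the correlation step."""


def pearson_matrix(X: pd.DataFrame, block_size: int | None = None) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix.

    Complete data are handled by standardizing rows and multiplying (optionally
    in row blocks of ``block_size``; results are block-size independent).
    Matrices with missing values fall back to pairwise-complete correlation.
    Raises :class:`ZeroVarianceError` naming the first offending gene.
    """
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    var = X.var(axis=1, ddof=0, skipna=True)
    bad = var.index[(var == 0) | var.isna()]
    if len(bad):
        raise ZeroVarianceError(f"zero-variance gene: {bad[0]}")
    if X.isna().any().any():
        R = X.T.corr(method="pearson", min_periods=3)
        return R
    vals = X.to_numpy(dtype=float)
    n = vals.shape[1]
    Z = vals - vals.mean(axis=1, keepdims=True)
    Z /= np.sqrt((Z**2).sum(axis=1, keepdims=True))
    m = Z.shape[0]
    if block_size is None or block_size >= m:
        R = Z @ Z.T
    else:
        R = np.empty((m, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            R[start:stop] = Z[start:stop] @ Z.T
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=X.index, columns=X.index)


def threshold_graph(
    R: pd.DataFrame, threshold: float = 0.90, drop_isolated: bool = True
) -> nx.Graph:
    """Build the co-expression graph keeping edges with |r| > threshold (strict).

    Nodes are gene ids; each edge carries the signed correlation as attribute
    ``r``. With ``drop_isolated`` (default) only genes with at least one edge
    become nodes.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    genes = list(R.index)
    A = R.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.abs(A[iu, ju]) > threshold
    G = nx.Graph()
    if not drop_isolated:
        G.add_nodes_from(genes)
    for i, j in zip(iu[keep], ju[keep]):
        G.add_edge(genes[i], genes[j], r=float(A[i, j]))
    return G


def topology_summary(G: nx.Graph) -> dict:
    """Node/edge counts, connected components, giant-component share (%),
    and the degree sequence (descending)."""
    n = G.number_of_nodes()
    if n == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "n_components": 0,
            "giant_pct": 0.0,
            "degrees": [],
        }
    comps = list(nx.connected_components(G))
    giant = max(len(c) for c in comps)
    return {
        "n_nodes": n,
        "n_edges": G.number_of_edges(),
        "n_components": len(comps),
        "giant_pct": 100.0 * giant / n,
        "degrees": sorted((d for _, d in G.degree()), reverse=True),
    }


def edge_table(G: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (gene_i < gene_j, signed r)."""
    rows = [
        {"gene_i": min(u, v), "gene_j": max(u, v), "r": d.get("r", 1.0)}
        for u, v, d in G.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_i", "gene_j", "r"])
    return df.sort_values(["gene_i", "gene_j"], ignore_index=True)
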