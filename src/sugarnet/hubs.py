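"""Degree / betweenness centrality and joint top-decile hub calling.

A hub is a node in the top ``top_fraction`` (default 10%) of BOTH degree and
betweenness. The threshold is the score of the floor(f*n)-th ranked node
(at least one) and ties at the threshold are kept (>=), so on degenerate
graphs (e.g. a regular ring where every node ties) the hub set may exceed
the nominal fraction — a deliberate, conservative rule. Hub calls are
rank-based and therefore invariant to the betweenness normalization
convention; raw scores reported here use unnormalized undirected pair
counting (each unordered source-target pair counted once).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .mcl import ModulePartition


def betweenness(G: nx.Graph) -> dict[str, float]:
    """Unweighted shortest-path betweenness (Brandes accumulation),
    unnormalized, undirected pair counting: the star S_5 center scores
    C(4,2) = 6."""
    return nx.betweenness_centrality(G, normalized=False)


def _rank_pct(values: np.ndarray) -> np.ndarray:
    """Percentile rank of each value (100 = maximum; ties share the mean rank)."""
    from scipy.stats import rankdata

    if len(values) == 0:
        return values
    return 100.0 * rankdata(values, method="average") / len(values)


def _top_cut(values: np.ndarray, top_fraction: float) -> float:
    """Smallest value among the top floor(f*n) nodes (at least one)."""
    k = max(1, int(np.floor(top_fraction * len(values))))
    return float(np.sort(values)[::-1][k - 1])


def _centrality_frame(G: nx.Graph, top_fraction: float) -> pd.DataFrame:
    nodes = sorted(G.nodes())
    deg = np.array([G.degree(n) for n in nodes], dtype=float)
    btw_map = betweenness(G)
    btw = np.array([btw_map[n] for n in nodes])
    hub = (deg >= _top_cut(deg, top_fraction)) & (btw >= _top_cut(btw, top_fraction))
    return pd.DataFrame(
        {
            "gene_id": nodes,
            "degree": deg.astype(int),
            "betweenness": btw,
            "degree_rank_pct": _rank_pct(deg),
            "betweenness_rank_pct": _rank_pct(btw),
            "hub": hub,
        }
    )


def call_hubs(
    G: nx.Graph,
    top_fraction: float = 0.10,
    scope: str = "global",
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """Centrality table with hub calls.

    ``scope='global'`` ranks within the whole graph; ``scope='per_module'``
    ranks within each module's induced subgraph (requires ``partition``) and
    adds a ``module`` column.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if scope == "global":
        return _centrality_frame(G, top_fraction)
    if scope != "per_module":
        raise ValueError("scope must be 'global' or 'per_module'")
    if partition is None:
        raise ValueError("per_module scope requires a partition")
    frames = []
    for label, members in sorted(partition.members.items()):
        sub = G.subgraph([m for m in members if m in G])
        if sub.number_of_nodes() == 0:
            continue
        f = _centrality_frame(sub, top_fraction)
        f.insert(1, "module", label)
        frames.append(f)
    if not frames:
        raise ValueError("partition shares no nodes with the graph")
    return pd.concat(frames, ignore_index=True)
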