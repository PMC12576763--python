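"""Markov Cluster Algorithm (MCL) for module detection, implemented from scratch.

MCL simulates flow on the graph: the column-stochastic transition matrix is
alternately *expanded* (matrix power, default square) and *inflated*
(entrywise power followed by column renormalization), with small entries
pruned between iterations. Flow concentrates within dense regions; the limit
matrix is read out as a clustering via its attractor rows. Inflation controls
granularity — the study value is 1.8.

Edge weights entering MCL are |r|: edges are retained by absolute correlation,
and MCL requires nonnegative input. Self-loops of weight 1 are added to every
node (standard regularization guaranteeing aperiodicity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx


class MCLConvergenceError(RuntimeError):
    """MCL did not reach the tolerance within max_iter iterations."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"MCL not converged after {max_iter} iterations (residual {residual:.3g})"
        )


@dataclass
class ModulePartition:
    """Gene -> module assignment with size-ordered positive-integer labels.

    Label 1 is a largest module; ties in size are broken by the
    lexicographically smallest member gene id. ``members`` maps label ->
    sorted member list.
    """

    assignment: dict[str, int]
    members: dict[int, list[str]]

    def __len__(self) -> int:
        return len(self.members)

    def sizes(self) -> dict[int, int]:
        return {label: len(m) for label, m in self.members.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "module": label}
            for label, genes in sorted(self.members.items())
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "module"])


def _column_normalize(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0, keepdims=True)
    colsum[colsum == 0] = 1.0
    return M / colsum


def mcl_cluster(
    G: nx.Graph,
    inflation: float = 1.8,
    expansion: int = 2,
    self_loop_weight: float = 1.0,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ModulePartition:
    """Cluster a co-expression graph with MCL.

    Edge weights are |r| read from the ``r`` edge attribute (absent attribute
    counts as weight 1). Raises on negative inflation/weights or
    non-convergence. Deterministic: output labels depend only on the graph.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    nodes = sorted(G.nodes())
    if not nodes:
        return ModulePartition(assignment={}, members={})
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, d in G.edges(data=True):
        w = abs(d["r"]) if "r" in d else d.get("weight", 1.0)
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    np.fill_diagonal(A, np.diag(A) + self_loop_weight)

    M = _column_normalize(A)
    residual = np.inf
    for _ in range(max_iter):
        M_new = np.linalg.matrix_power(M, expansion)
        M_new = _column_normalize(np.power(M_new, inflation))
        M_new[M_new < prune_threshold] = 0.0
        M_new = _column_normalize(M_new)
        residual = float(np.max(np.abs(M_new - M)))
        M = M_new
        if residual < tol:
            break
    else:
        raise MCLConvergenceError(residual, max_iter)

    return _read_clusters(M, nodes)


def _read_clusters(M: np.ndarray, nodes: list[str]) -> ModulePartition:
    """Interpret the MCL limit matrix.

    Attractors are rows with mass on their own diagonal; attractor rows whose
    supports overlap belong to one attractor system (cluster). Each node joins
    the system holding most of its limiting column mass; exact ties go to the
    system whose smallest member gene id sorts first (deterministic).
    """
    n = len(nodes)
    eps = 1e-9
    attractors = np.flatnonzero(np.diag(M) > eps)
    if attractors.size == 0:  # degenerate; treat every node as its own cluster
        attractors = np.arange(n)
    # union-find over attractors sharing any column support
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    support = {int(a): set(np.flatnonzero(M[a] > eps)) for a in attractors}
    att = [int(a) for a in attractors]
    for i, a in enumerate(att):
        for b in att[i + 1 :]:
            if support[a] & support[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    systems: dict[int, list[int]] = {}
    for a in att:
        systems.setdefault(find(a), []).append(a)

    cluster_nodes: dict[int, set[int]] = {root: set() for root in systems}
    for j in range(n):
        masses = {
            root: sum(M[a, j] for a in rows) for root, rows in systems.items()
        }
        best = max(masses.values())
        if best <= eps:
            # untouched by any attractor (should not happen with self-loops):
            # make the node its own singleton system
            cluster_nodes.setdefault(-j - 1, set()).add(j)
            continue
        candidates = [root for root, m in masses.items() if m >= best - eps]
        if len(candidates) > 1:
            # tie: deterministic — the system whose smallest attractor sorts first
            candidates.sort(key=lambda r: min(nodes[a] for a in systems[r]))
        cluster_nodes[candidates[0]].add(j)

    groups = [sorted(nodes[i] for i in idxs) for idxs in cluster_nodes.values() if idxs]
    groups.sort(key=lambda g: (-len(g), g[0]))
    assignment: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    for label, genes in enumerate(groups, start=1):
        members[label] = genes
        for g in genes:
            assignment[g] = label
    return ModulePartition(assignment=assignment, members=members)


def module_size_stats(partition: ModulePartition, n_network_nodes: int | None = None) -> dict:
    """Summary of the module size distribution.

    ``n_network_nodes`` defaults to the number of clustered genes; shares are
    percentages of it. Reports min/max size, the largest and second-largest
    module shares, and the count/fraction of modules with more than 10 nodes.
    """
    if len(partition) == 0:
        raise ValueError("empty partition")
    sizes = sorted(partition.sizes().values(), reverse=True)
    total = n_network_nodes if n_network_nodes is not None else sum(sizes)
    over10 = sum(1 for s in sizes if s > 10)
    return {
        "n_modules": len(sizes),
        "min_size": sizes[-1],
        "max_size": sizes[0],
        "largest_share_pct": 100.0 * sizes[0] / total,
        "second_share_pct": 100.0 * sizes[1] / total if len(sizes) > 1 else 0.0,
        "n_over_10": over10,
        "over_10_pct": 100.0 * over10 / len(sizes),
    }
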