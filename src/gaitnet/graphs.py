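"""Graph-theoretic measures of the thresholded dDTF network.

Distances are shortest-path hop counts from breadth-first search. The four
summary measures are:

* characteristic path length PL — mean of the finite off-diagonal d_ij
  (unreachable pairs are excluded and counted, not set to infinity);
* global efficiency E_glob — mean of 1/d_ij with 1/inf = 0, so isolated
  nodes penalize rather than poison the average;
* clustering coefficient cl_i = 2 e_i / (k_i (k_i - 1)) on the undirected
  graph, CL_a the node mean (nodes of degree < 2 get cl_i = 0);
* local efficiency E_loc — mean over nodes of the global efficiency of the
  subgraph induced on each node's neighbours.

dDTF adjacencies are directed; PL / E_glob / nodal PL run on the directed
graph by default while clustering / local efficiency require a symmetrized
(OR) adjacency. Both modes are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_sp


class DisconnectedGraphError(ValueError):
    """No reachable pair exists; the requested measure is undefined."""


def _check_adjacency(adjacency: np.ndarray, require_symmetric: bool = False) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if require_symmetric and not np.array_equal(a, a.T):
        raise ValueError("this measure needs an undirected (symmetric) adjacency; "
                         "symmetrize first")
    return a.astype(float)


def symmetrize(adjacency: np.ndarray) -> np.ndarray:
    """Undirected version: edge wherever either direction has one (OR)."""
    a = np.asarray(adjacency)
    return ((a + a.T) > 0).astype(int)


def shortest_paths(adjacency: np.ndarray, directed: bool = True) -> np.ndarray:
    """Hop-count distance matrix by BFS from every node; unreachable = inf."""
    a = _check_adjacency(adjacency)
    d = _csgraph_sp(a, method="D", directed=directed, unweighted=True)
    np.fill_diagonal(d, 0.0)
    return d


def characteristic_path_length(d_matrix: np.ndarray) -> tuple[float, int]:
    """Mean finite off-diagonal distance; also returns the count of
    unreachable ordered pairs (excluded from the mean)."""
    d = np.asarray(d_matrix, dtype=float)
    off = ~np.eye(d.shape[0], dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    n_unreachable = int((~finite).sum())
    if not finite.any():
        raise DisconnectedGraphError("no reachable pair: PL undefined")
    return float(vals[finite].mean()), n_unreachable


def global_efficiency(d_matrix: np.ndarray) -> float:
    """Mean over ordered pairs i != j of 1/d_ij, with 1/inf = 0."""
    d = np.asarray(d_matrix, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def clustering(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering cl_i and network mean CL_a (undirected input).

    cl_i = 2 e_i / (k_i (k_i - 1)) with e_i the number of edges among the
    neighbours of i; nodes with fewer than two neighbours get cl_i = 0.
    """
    a = _check_adjacency(adjacency, require_symmetric=True)
    n = a.shape[0]
    k = a.sum(axis=1)
    # paths i-j-m with j,m both neighbours of i: (A^3)_ii counts 2*e_i
    tri = np.diagonal(a @ a @ a)
    cl = np.zeros(n)
    mask = k >= 2
    cl[mask] = tri[mask] / (k[mask] * (k[mask] - 1))
    return cl, float(cl.mean())


def local_efficiency(adjacency: np.ndarray, directed: bool = False) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    a = _check_adjacency(adjacency)
    und = symmetrize(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(und[i])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)].astype(int)
        d = shortest_paths(sub, directed=directed)
        total += global_efficiency(d)
    return total / n


def nodal_path_length(d_matrix: np.ndarray, node: int) -> float:
    """Mean finite distance from *node* to every other node (outgoing)."""
    d = np.asarray(d_matrix, dtype=float)
    n = d.shape[0]
    if not (0 <= node < n):
        raise ValueError(f"node {node} out of range")
    row = np.delete(d[node], node)
    finite = np.isfinite(row)
    if not finite.any():
        raise DisconnectedGraphError(f"node {node} reaches no other node")
    return float(row[finite].mean())


@dataclass
class GraphMetrics:
    """All measures of one network."""

    path_length: float
    n_unreachable: int
    global_eff: float
    clustering_per_node: np.ndarray
    clustering_avg: float
    local_eff: float
    nodal_pl: np.ndarray
    d_matrix: np.ndarray
    degrees: np.ndarray

    def summary(self) -> str:
        return "\n".join([
            "Graph metrics",
            "=" * 30,
            f"characteristic path length: {self.path_length:.4f}"
            f"  (unreachable pairs: {self.n_unreachable})",
            f"global efficiency:          {self.global_eff:.4f}",
            f"clustering coefficient:     {self.clustering_avg:.4f}",
            f"local efficiency:           {self.local_eff:.4f}",
        ])


def graph_metrics(adjacency: np.ndarray, directed: bool = True,
                  impute_nodal: bool = True) -> GraphMetrics:
    """Compute all measures: PL / E_glob / nodal PL on the graph as given
    (directed by default), clustering and local efficiency on the OR-
    symmetrized graph as their formulas require.

    With ``impute_nodal``, nodes reaching nothing get the max finite nodal
    value + 1 instead of raising (feature extraction needs finite vectors).
    """
    a = _check_adjacency(adjacency).astype(int)
    und = symmetrize(a)
    d = shortest_paths(a, directed=directed)
    try:
        pl, n_unreach = characteristic_path_length(d)
    except DisconnectedGraphError:
        # empty graph: flag with NaN PL, count all pairs unreachable
        pl, n_unreach = float("nan"), a.shape[0] * (a.shape[0] - 1)
    eg = global_efficiency(d)
    cl, cla = clustering(und)
    el = local_efficiency(und, directed=False)
    n = a.shape[0]
    nodal = np.full(n, np.nan)
    for i in range(n):
        try:
            nodal[i] = nodal_path_length(d, i)
        except DisconnectedGraphError:
            pass
    if impute_nodal and np.isnan(nodal).any():
        finite_vals = nodal[~np.isnan(nodal)]
        fill = finite_vals.max() + 1.0 if finite_vals.size else float(n)
        nodal = np.where(np.isnan(nodal), fill, nodal)
    return GraphMetrics(pl, n_unreach, eg, cl, cla, el, nodal, d,
                        und.sum(axis=1))
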