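"""Confidence-filtered interaction graphs and Markov clustering (MCL).

The graph is the subgraph of a STRING-style weighted edge list induced on a
marker set, keeping only edges whose combined confidence exceeds a threshold
(0.7 by default, strict). MCL partitions it by alternating expansion
(matrix squaring of the column-stochastic transition matrix) and inflation
(elementwise powering with column renormalization) until the matrix stops
changing; clusters are read off the attractor structure of the limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .autoencoder import MarkerSet


def build_graph(
    edges: Iterable[tuple[str, str, float]],
    markers: MarkerSet | Sequence[str],
    min_conf: float = 0.7,
) -> nx.Graph:
    """Induced marker subgraph with edges of confidence strictly > min_conf.

    ``edges`` yields (node, node, score) with scores in [0, 1]; raw STRING
    integer scores in [0, 1000] are rescaled by the caller (see
    :func:`sparseae.io.read_edges`). Self-loops are dropped and duplicate
    edges keep the maximum score. Every marker appears as a node even if
    isolated.
    """
    marker_ids = list(markers.gene_ids if isinstance(markers, MarkerSet) else markers)
    marker_set = set(marker_ids)
    G = nx.Graph()
    G.add_nodes_from(marker_ids)
    for row_no, edge in enumerate(edges, start=1):
        try:
            u, v, score = edge
            score = float(score)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge row {row_no}: {edge!r}") from exc
        if not (0.0 <= score <= 1.0):
            raise ValueError(
                f"edge row {row_no}: score {score} outside [0, 1] "
                "(rescale raw 0-1000 scores first)"
            )
        if u == v:
            continue
        if u not in marker_set or v not in marker_set:
            continue
        if score <= min_conf:
            continue
        if G.has_edge(u, v):
            G[u][v]["weight"] = max(G[u][v]["weight"], score)
        else:
            G.add_edge(u, v, weight=score)
    return G


@dataclass
class ModulePartition:
    """Disjoint node clusters from MCL; ``inflation`` records the setting."""

    clusters: list[list[str]]
    inflation: float
    converged: bool = True
    n_iter: int = 0
    column_sum_history: list[float] = field(default_factory=list)

    def modules_larger_than(self, min_size: int = 2) -> list[list[str]]:
        """Modules with more than ``min_size`` genes (reporting convention)."""
        return [c for c in self.clusters if len(c) > min_size]

    def membership(self) -> dict[str, int]:
        return {g: i for i, c in enumerate(self.clusters) for g in c}


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return M / colsum


def mcl(
    graph: nx.Graph,
    inflation: float = 2.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
    self_loop_weight: float = 1.0,
    record_column_sums: bool = False,
) -> ModulePartition:
    """Markov clustering of a weighted undirected graph.

    Self-loops of ``self_loop_weight`` are added before column
    normalization (standard practice; guarantees convergence on bipartite
    structures). Each iteration squares the matrix (expansion), raises it
    elementwise to ``inflation`` and renormalizes columns (inflation), and
    zeroes entries below ``prune``. Iteration stops when the max absolute
    change falls below ``tol`` or after ``max_iter`` sweeps (warning, the
    current partition is still returned).

    Every node lands in exactly one cluster: it joins the attractor system
    holding the largest share of its column mass, ties to the lowest node id.
    """
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("graph is empty")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    A[np.diag_indices(n)] += self_loop_weight
    M = _normalize_columns(A)

    converged = False
    col_sums: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        M_new = _normalize_columns(np.power(M @ M, inflation))
        M_new[M_new < prune] = 0.0
        M_new = _normalize_columns(M_new)
        if record_column_sums:
            col_sums.append(float(np.abs(M_new.sum(axis=0) - 1.0).max()))
        diff = float(np.abs(M_new - M).max())
        M = M_new
        if diff < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations", stacklevel=2
        )

    attractors = [i for i in range(n) if M[i, i] > tol]
    if not attractors:
        attractors = [int(np.argmax(M.sum(axis=1)))]
    # Attractor systems: attractors sharing positive mass form one cluster.
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > 0 or M[j, i] > 0):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda c: c[0])
    sys_of_attractor = {a: s for s, comp in enumerate(systems) for a in comp}

    assignment: dict[int, int] = {}
    for j in range(n):
        masses: dict[int, float] = {}
        for a in attractors:
            if M[a, j] > 0:
                s = sys_of_attractor[a]
                masses[s] = masses.get(s, 0.0) + M[a, j]
        if masses:
            best = max(masses.items(), key=lambda kv: (kv[1], -kv[0]))
            assignment[j] = best[0]
        else:  # no attractor mass (pruned away): singleton
            assignment[j] = -1 - j
    clusters_idx: dict[int, list[int]] = {}
    for j, s in assignment.items():
        clusters_idx.setdefault(s, []).append(j)
    clusters = [sorted(nodes[j] for j in members) for members in clusters_idx.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return ModulePartition(clusters, inflation, converged, it, col_sums)
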