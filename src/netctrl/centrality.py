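"""Per-node centralities on signed directed coupling matrices.

Covers graph measures (absolute in/out strength, their ratio, PageRank on the
binarized digraph), Gramian-trace control centralities, energy centralities
derived from the pairwise energy matrix, inverse-weight shortest paths, and
propagator-based coupling scores.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .connectome import (AccessibilityVector, EffectiveConnectome,
                         FunctionalConnectome, spectral_abscissa)
from .errors import ParameterError, StabilityError
from .gramian import PairwiseEnergyMatrix, pairwise_energies

#: How each centrality orders candidate drivers (best first).
#: Low pairwise driver energy and low PageRank are preferred; strength-like
#: scores are preferred high.
CENTRALITY_DIRECTIONS = {
    "driver_energy": "ascending",
    "target_energy": "ascending",
    "out_strength": "descending",
    "in_strength": "descending",
    "ratio": "descending",
    "pq": "descending",
    "pagerank": "ascending",
    "fc_strength": "descending",
}


def strength_centralities(ec: EffectiveConnectome,
                          include_diagonal: bool = False) -> pd.DataFrame:
    """Absolute in-/out-strengths and their ratio.

    ``out_strength(i) = sum_j |A_ji|`` and ``in_strength(i) = sum_j |A_ij|``
    (the diagonal encodes leak/decay and is excluded by default).  The ratio
    is +inf where the in-strength vanishes.
    """
    absA = np.abs(ec.A).astype(float)
    if not include_diagonal:
        absA = absA.copy()
        np.fill_diagonal(absA, 0.0)
    in_strength = absA.sum(axis=1)
    out_strength = absA.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(in_strength > 0, out_strength / in_strength, np.inf)
    return pd.DataFrame({"in_strength": in_strength,
                         "out_strength": out_strength,
                         "ratio": ratio})


def binarized_digraph(A: np.ndarray) -> nx.DiGraph:
    """Directed unweighted graph with an edge j -> i wherever ``A_ij != 0``
    (off-diagonal only)."""
    n = A.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(A)
    G.add_edges_from((int(j), int(i)) for i, j in zip(rows, cols) if i != j)
    return G


def pagerank_centrality(ec: EffectiveConnectome, damping: float = 0.85) -> np.ndarray:
    """PageRank on the binarized influence digraph; scores sum to 1."""
    if not 0 < damping < 1:
        raise ParameterError("damping must be in (0, 1)")
    G = binarized_digraph(ec.A)
    pr = nx.pagerank(G, alpha=damping, tol=1e-12, max_iter=500)
    return np.array([pr[i] for i in range(ec.n)])


def pq_centrality(ec: EffectiveConnectome,
                  accessibility: AccessibilityVector | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gramian-trace control centrality: ``p_i / q_i``.

    ``p_i`` is the trace of the single-driver controllability Gramian of node
    ``i`` (so it scales exactly with the squared accessibility weight of the
    driver column), ``q_i`` the trace of its single-target observability
    Gramian.  Both traces for all nodes come from two Lyapunov solves, since
    ``tr W^(i) = [Q]_ii`` with ``A'Q + QA + I = 0`` and ``tr M^(i) = [P]_ii``
    with ``AP + PA' + I = 0``.
    """
    A = ec.A
    if spectral_abscissa(A) > -1e-6:
        raise StabilityError("pq centrality requires stable dynamics")
    n = ec.n
    Q = solve_continuous_lyapunov(A.T, -np.eye(n))
    P = solve_continuous_lyapunov(A, -np.eye(n))
    p = np.diag(Q).copy()
    q = np.diag(P).copy()
    if accessibility is not None:
        p = accessibility.beta**2 * p
    return p, q, p / q


def energy_centralities(pe: PairwiseEnergyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Driver and target energy centralities: row/column means of the
    pairwise energy matrix (the self pair included; +inf propagates)."""
    n = pe.E.shape[0]
    driver_energy = pe.E.sum(axis=1) / n
    target_energy = pe.E.sum(axis=0) / n
    return driver_energy, target_energy


def shortest_paths(ec: EffectiveConnectome) -> np.ndarray:
    """All-pairs shortest path lengths with edge length ``1/|A|``.

    ``lengths[i, j]`` is the shortest distance from ``i`` to ``j`` following
    influence edges (edge i -> j exists iff ``A_ji != 0``); +inf where
    unreachable, 0 on the diagonal.
    """
    A = ec.A
    with np.errstate(divide="ignore"):
        inv = np.where(A != 0.0, 1.0 / np.abs(A), 0.0)
    np.fill_diagonal(inv, 0.0)
    # graph[u, v] = weight of edge u -> v = 1/|A_vu|
    graph = inv.T
    return _dijkstra(graph, directed=True)


def propagator_coupling(ec: EffectiveConnectome, T: float = 10.0) -> np.ndarray:
    """Matrix exponential ``exp(A T)``: entry ``(j, i)`` integrates direct and
    indirect influence of node ``i`` on node ``j`` over horizon ``T``."""
    if T <= 0:
        raise ParameterError("horizon T must be positive")
    return expm(ec.A * T)


def fc_strength(fc: FunctionalConnectome) -> np.ndarray:
    """Row sums of the correlation matrix excluding the unit diagonal."""
    return fc.F.sum(axis=1) - np.diag(fc.F)


def centrality_table(ec: EffectiveConnectome,
                     fc: FunctionalConnectome | None = None,
                     pe: PairwiseEnergyMatrix | None = None,
                     accessibility: AccessibilityVector | None = None,
                     damping: float = 0.85) -> pd.DataFrame:
    """Assemble the full per-node centrality table (one row per node)."""
    table = strength_centralities(ec)
    table["pagerank"] = pagerank_centrality(ec, damping)
    p, q, pq = pq_centrality(ec, accessibility)
    table["p"], table["q"], table["pq"] = p, q, pq
    if pe is None:
        pe = pairwise_energies(ec)
    ed, et = energy_centralities(pe)
    table["driver_energy"], table["target_energy"] = ed, et
    if fc is not None:
        table["fc_strength"] = fc_strength(fc)
    table.insert(0, "node_id", np.arange(ec.n))
    return table


def compute_centrality(ec: EffectiveConnectome, name: str,
                       fc: FunctionalConnectome | None = None,
                       pe: PairwiseEnergyMatrix | None = None,
                       accessibility: AccessibilityVector | None = None) -> np.ndarray:
    """Score vector for a named centrality (see CENTRALITY_DIRECTIONS)."""
    if name in ("in_strength", "out_strength", "ratio"):
        return strength_centralities(ec)[name].to_numpy()
    if name == "pagerank":
        return pagerank_centrality(ec)
    if name == "pq":
        return pq_centrality(ec, accessibility)[2]
    if name in ("driver_energy", "target_energy"):
        if pe is None:
            pe = pairwise_energies(ec)
        ed, et = energy_centralities(pe)
        return ed if name == "driver_energy" else et
    if name == "fc_strength":
        if fc is None:
            raise ParameterError("fc_strength requires a FunctionalConnectome")
        return fc_strength(fc)
    raise ParameterError(f"unknown centrality {name!r}")
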