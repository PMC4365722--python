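"""Spectral modularity maximization (leading-eigenvector bisection).

Communities are found by recursively bisecting the graph along the
leading eigenvector of the modularity matrix

    B_ij = A_ij - k_i k_j / (2m),

where A is the binary adjacency, k the degree vector and m the edge
count. The modularity of a partition,

    Q = (1/2m) sum_ij B_ij [c_i == c_j],

measures the excess of within-community edges over the expectation in a
degree-preserving random graph. A bisection is encoded by a sign vector
s in {-1, +1}^P with modularity change dQ = s^T B s / (4m); taking s
from the signs of the leading eigenvector of B maximizes a relaxation of
this quadratic form. The split is then refined by a Kernighan-Lin style
sweep (each vertex moved at most once per sweep, always the currently
best move, the best intermediate state kept) and accepted only if
dQ > 0. Subdivision recurses with the generalized subgraph matrix

    B(g)_ij = B_ij - delta_ij * sum_{l in g} B_il,

whose rows again sum to zero over g, so that dQ of a sub-split is exact
and never forced: a subgraph whose B(g) has no positive eigenvalue is
indivisible. The algorithm is deterministic (dense symmetric
eigendecomposition with a canonical eigenvector sign, lowest-index tie
break in the sweep).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from .cohort import CompoundMatrix
from .similarity import SimilarityGraph, apply_threshold, build_icc_matrix, max_connected_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "DisconnectedGraphError",
    "Graph",
    "Partition",
    "modularity_q",
    "modularity_matrix",
    "subgraph_modularity_matrix",
    "leading_split",
    "fine_tune",
    "detect_communities",
    "threshold_robustness",
]


class DisconnectedGraphError(ValueError):
    """Community detection requires a connected graph; re-select the threshold."""


@dataclasses.dataclass
class Graph:
    """Simple undirected graph given by a binary symmetric adjacency."""

    adjacency: np.ndarray
    degrees: np.ndarray = dataclasses.field(init=False)
    m_edges: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A
        self.degrees = A.sum(axis=1)
        self.m_edges = float(self.degrees.sum() / 2.0)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1


@dataclasses.dataclass
class Partition:
    """Community labels with modularity Q and a per-bisection audit trail."""

    labels: np.ndarray
    q: float
    split_tree: list[dict] = dataclasses.field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def community_sizes(self) -> list[int]:
        return np.bincount(self.labels).tolist()

    def to_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        index = pd.Index(ids if ids is not None else range(len(self.labels)), name="id")
        return pd.DataFrame({"community": self.labels}, index=index)


def modularity_q(graph: Graph, labels: Sequence[int]) -> float:
    """Newman-Girvan modularity Q of a labelling."""
    labels = np.asarray(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError("labels must cover every node")
    if graph.m_edges == 0:
        raise ValueError("graph has no edges; modularity undefined")
    B = modularity_matrix(graph)
    same = labels[:, None] == labels[None, :]
    return float((B * same).sum() / (2.0 * graph.m_edges))


def modularity_matrix(graph: Graph) -> np.ndarray:
    """B = A - k k^T / 2m; rows sum to zero."""
    if graph.m_edges == 0:
        raise ValueError("graph has no edges; modularity matrix undefined")
    k = graph.degrees
    return graph.adjacency - np.outer(k, k) / (2.0 * graph.m_edges)


def subgraph_modularity_matrix(B: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Generalized B(g): restrict B to g and re-center the diagonal."""
    Bg = B[np.ix_(g, g)].copy()
    Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
    return Bg


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Fix the eigenvector sign: the largest-magnitude component is positive."""
    pivot = int(np.argmax(np.abs(v)))
    return -v if v[pivot] < 0 else v


def leading_split(
    graph: Graph,
    g: np.ndarray,
    B: np.ndarray | None = None,
    eigen_tol: float = 1e-10,
    sign_tol: float = 1e-12,
) -> tuple[np.ndarray, float, float] | None:
    """Propose a bisection of node subset *g* from the leading eigenpair of B(g).

    Returns ``(s, lambda_max, delta_q)`` with ``s`` in {-1,+1}^|g|
    (components within *sign_tol* of zero get +1), or ``None`` when the
    subset is indivisible (``lambda_max <= eigen_tol``).
    """
    g = np.asarray(g)
    if len(g) < 2:
        raise ValueError("need at least 2 nodes to split")
    if B is None:
        B = modularity_matrix(graph)
    Bg = subgraph_modularity_matrix(B, g)
    eigvals, eigvecs = np.linalg.eigh(Bg)
    lam = float(eigvals[-1])
    if lam <= eigen_tol:
        return None
    v = _canonical_sign(eigvecs[:, -1])
    s = np.where(v < -sign_tol, -1.0, 1.0)
    dq = float(s @ Bg @ s) / (4.0 * graph.m_edges)
    return s, lam, dq


def fine_tune(
    graph: Graph,
    g: np.ndarray,
    s: np.ndarray,
    B: np.ndarray | None = None,
    fine_tune_tol: float = 1e-12,
) -> np.ndarray:
    """Kernighan-Lin refinement of a bisection; never decreases dQ.

    Repeated sweeps: within a sweep every vertex is sign-flipped at most
    once, each step taking the move with the largest dQ gain (ties go to
    the lowest node index); the best intermediate state of the sweep is
    kept. Sweeps repeat until the improvement is <= *fine_tune_tol*.
    """
    g = np.asarray(g)
    if B is None:
        B = modularity_matrix(graph)
    Bg = subgraph_modularity_matrix(B, g)
    m = graph.m_edges
    diag = np.diag(Bg).copy()
    s = np.asarray(s, dtype=float).copy()

    def dq_of(vec: np.ndarray) -> float:
        return float(vec @ Bg @ vec) / (4.0 * m)

    current_best = dq_of(s)
    while True:
        cur = s.copy()
        Bs = Bg @ cur
        curq = dq_of(cur)
        moved = np.zeros(len(g), dtype=bool)
        sweep_best_q = current_best
        sweep_best_state: np.ndarray | None = None
        for _ in range(len(g)):
            # gain of flipping vertex i: (B_ii - s_i (B s)_i) / m
            gains = (diag - cur * Bs) / m
            gains[moved] = -np.inf
            i = int(np.argmax(gains))  # argmax takes the lowest index on ties
            curq += gains[i]
            Bs = Bs - 2.0 * cur[i] * Bg[:, i]
            cur[i] = -cur[i]
            moved[i] = True
            if curq > sweep_best_q:
                sweep_best_q = curq
                sweep_best_state = cur.copy()
        if sweep_best_state is None or sweep_best_q - current_best <= fine_tune_tol:
            break
        s = sweep_best_state
        current_best = sweep_best_q
    return s


def detect_communities(
    graph: Graph,
    eigen_tol: float = 1e-10,
    fine_tune_tol: float = 1e-12,
    refine: bool = True,
) -> Partition:
    """Full recursive spectral modularity maximization.

    Splits are accepted only when they strictly increase Q; recursion
    uses the generalized B(g) so sub-split gains are exact. The returned
    ``Partition.q`` is recomputed from the final labels (consistency with
    the accumulated dQ is within 1e-12).
    """
    if not graph.is_connected():
        raise DisconnectedGraphError(
            "graph is disconnected; choose a lower similarity threshold (reachability < 1)")
    B = modularity_matrix(graph)
    P = graph.n_nodes
    labels = np.zeros(P, dtype=int)
    split_tree: list[dict] = []
    next_label = 1
    stack: list[np.ndarray] = [np.arange(P)]
    while stack:
        g = stack.pop()
        if len(g) < 2:
            continue
        proposal = leading_split(graph, g, B, eigen_tol=eigen_tol)
        if proposal is None:
            split_tree.append({"nodes": len(g), "lambda_max": None, "delta_q": 0.0,
                               "accepted": False, "reason": "indivisible"})
            continue
        s, lam, dq = proposal
        if refine:
            s = fine_tune(graph, g, s, B, fine_tune_tol=fine_tune_tol)
            Bg = subgraph_modularity_matrix(B, g)
            dq = float(s @ Bg @ s) / (4.0 * graph.m_edges)
        if dq <= 0 or np.all(s == s[0]):
            split_tree.append({"nodes": len(g), "lambda_max": lam, "delta_q": dq,
                               "accepted": False, "reason": "no modularity gain"})
            continue
        g_pos = g[s > 0]
        g_neg = g[s < 0]
        labels[g_neg] = next_label
        next_label += 1
        split_tree.append({"nodes": len(g), "lambda_max": lam, "delta_q": dq,
                           "accepted": True, "sizes": [len(g_pos), len(g_neg)]})
        stack.append(g_neg)
        stack.append(g_pos)

    # relabel communities 0..k-1 in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    order = {}
    for lab in labels:
        order.setdefault(int(lab), len(order))
    labels = np.array([order[int(lab)] for lab in labels], dtype=int)

    q = modularity_q(graph, labels)
    accumulated = sum(e["delta_q"] for e in split_tree if e["accepted"])
    if abs(q - accumulated) > 1e-9:
        raise AssertionError(f"modularity bookkeeping drifted: Q={q} vs sum dQ={accumulated}")
    logger.info("detected %d communities, Q = %.4f", len(np.unique(labels)), q)
    return Partition(labels=labels, q=q, split_tree=split_tree)


def threshold_robustness(
    scores: CompoundMatrix,
    thresholds: Sequence[float],
    eigen_tol: float = 1e-10,
    fine_tune_tol: float = 1e-12,
    similarity: SimilarityGraph | None = None,
) -> tuple[pd.DataFrame, dict[float, Partition]]:
    """Re-run detection at several ICC thresholds and compare partitions.

    Returns a table with one row per threshold (reachability, community
    count, sizes, Q, ARI against the first partitioned threshold, and a
    stability flag) plus the partitions themselves. Thresholds that
    disconnect the graph are reported with a warning and skipped.
    """
    sim = similarity if similarity is not None else build_icc_matrix(scores)
    rows = []
    partitions: dict[float, Partition] = {}
    reference: Partition | None = None
    for t in thresholds:
        thr = apply_threshold(sim, t)
        if thr.reachability < 1.0:
            warnings.warn(f"threshold {t:.4f} disconnects the graph "
                          f"(reachability {thr.reachability:.3f}); partition skipped")
            rows.append({"threshold": t, "reachability": thr.reachability,
                         "n_communities": None, "sizes": None, "q": None, "ari_vs_first": None})
            continue
        part = detect_communities(Graph(thr.adjacency), eigen_tol, fine_tune_tol)
        partitions[float(t)] = part
        ari = adjusted_rand_score(reference.labels, part.labels) if reference is not None else 1.0
        if reference is None:
            reference = part
        rows.append({"threshold": t, "reachability": thr.reachability,
                     "n_communities": part.n_communities,
                     "sizes": part.community_sizes(), "q": part.q, "ari_vs_first": ari})
    table = pd.DataFrame(rows)
    counts = {r["n_communities"] for r in rows if r["n_communities"] is not None}
    table.attrs["stable_community_count"] = len(counts) <= 1
    if len(counts) > 1:
        warnings.warn(f"community count varies across thresholds: {sorted(counts)}")
    return table, partitions
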