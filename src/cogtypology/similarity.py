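"""Pairwise ICC(A,1) similarity and graph thresholding.

Similarity between two participants is the intraclass correlation
coefficient for a two-way model with absolute agreement and single
measures, ICC(A,1). The two participants' oriented z-score profiles are
arranged as an n x 2 table (the n = 8 compound scores as rows/targets,
the participants as columns/raters) and decomposed by two-way ANOVA:

    SS_R  rows (scores),        df = n - 1,  MS_R
    SS_C  columns (people),     df = k - 1,  MS_C      (k = 2)
    SS_E  residual,             df = (n-1)(k-1), MS_E

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

Absolute agreement matters here: two participants with the same *shape*
of profile but a constant offset are less similar than identical
profiles, which a consistency ICC or Pearson correlation would not see.

The complete symmetric ICC matrix is thresholded into a binary graph.
The canonical threshold t* is the largest ICC value at which the graph is
still connected ("reachability" 1: every participant reaches every
other); it equals the bottleneck (minimum) edge weight of a maximum
spanning tree of the ICC-weighted complete graph.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components

from .cohort import CompoundMatrix

__all__ = [
    "UndefinedSimilarityError",
    "ICCResult",
    "SimilarityGraph",
    "icc_a1_pair",
    "build_icc_matrix",
    "max_connected_threshold",
    "apply_threshold",
    "to_networkx",
    "write_edge_list",
    "write_graphml",
]

_DENOM_TOL = 1e-12


class UndefinedSimilarityError(ValueError):
    """ICC denominator is zero (both profiles constant and equal)."""


@dataclasses.dataclass
class ICCResult:
    """ICC(A,1) plus its two-way ANOVA mean squares."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_rows: int
    n_cols: int = 2


@dataclasses.dataclass
class SimilarityGraph:
    """Symmetric pairwise ICC matrix with an optional thresholded adjacency."""

    ids: list[str]
    icc_matrix: np.ndarray          # P x P, diagonal NaN (self-similarity undefined)
    threshold: float | None = None
    adjacency: np.ndarray | None = None
    reachability: float | None = None

    @property
    def n(self) -> int:
        return len(self.ids)


def icc_a1_pair(x: np.ndarray, y: np.ndarray) -> ICCResult:
    """ICC(A,1) between two equal-length score vectors (n >= 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("icc_a1_pair needs two 1-d vectors of equal length >= 2")
    n, k = len(x), 2
    grand = (x.mean() + y.mean()) / 2.0
    row_means = (x + y) / 2.0
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * ((x.mean() - grand) ** 2 + (y.mean() - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2) + np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) < _DENOM_TOL:
        raise UndefinedSimilarityError("all table cells equal; ICC(A,1) is 0/0")
    return ICCResult(icc=(ms_r - ms_e) / denom, ms_rows=ms_r, ms_cols=ms_c,
                     ms_error=ms_e, n_rows=n)


def build_icc_matrix(scores: CompoundMatrix) -> SimilarityGraph:
    """All-pairs ICC(A,1) over the rows of a compound matrix (vectorized).

    Equivalent to calling :func:`icc_a1_pair` on every row pair. Raises
    :class:`UndefinedSimilarityError` listing the offending id pairs if
    any pair has an undefined ICC.
    """
    Z = np.asarray(scores.scores, dtype=float)
    P, n = Z.shape
    if P < 2:
        raise ValueError("need at least 2 participants")
    k = 2.0
    u = Z.mean(axis=1)                                    # per-participant means
    grand = (u[:, None] + u[None, :]) / 2.0               # pairwise grand means
    row_means = (Z[:, None, :] + Z[None, :, :]) / 2.0     # P x P x n
    ss_rows = k * ((row_means - grand[:, :, None]) ** 2).sum(axis=2)
    ss_cols = n * (u[:, None] - u[None, :]) ** 2 / 2.0
    dev = Z[:, None, :] - grand[:, :, None]
    devT = Z[None, :, :] - grand[:, :, None]
    ss_total = (dev ** 2).sum(axis=2) + (devT ** 2).sum(axis=2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = np.maximum(ss_total - ss_rows - ss_cols, 0.0) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)

    off = ~np.eye(P, dtype=bool)
    bad = off & (np.abs(denom) < _DENOM_TOL)
    if bad.any():
        ii, jj = np.where(np.triu(bad, 1))
        pairs = [(scores.ids[i], scores.ids[j]) for i, j in zip(ii, jj)]
        raise UndefinedSimilarityError(f"undefined ICC for participant pairs: {pairs}")

    icc = np.where(off, (ms_r - ms_e) / np.where(off, denom, 1.0), np.nan)
    icc = (icc + icc.T) / 2.0  # symmetric up to float noise by construction
    np.fill_diagonal(icc, np.nan)
    return SimilarityGraph(ids=list(scores.ids), icc_matrix=icc)


def max_connected_threshold(graph: SimilarityGraph) -> float:
    """Largest threshold t* at which the edge set {icc >= t*} stays connected.

    Computed as the bottleneck edge of a maximum spanning tree of the
    ICC-weighted complete graph: thresholding at that bottleneck keeps
    the tree (hence connectivity); any higher threshold cuts it.
    """
    P = graph.n
    if P < 2:
        raise ValueError("need at least 2 participants to threshold")
    g = nx.Graph()
    g.add_nodes_from(range(P))
    icc = graph.icc_matrix
    for i in range(P):
        for j in range(i + 1, P):
            g.add_edge(i, j, weight=float(icc[i, j]))
    mst = nx.maximum_spanning_tree(g, weight="weight")
    return min(d["weight"] for _, _, d in mst.edges(data=True))


def apply_threshold(graph: SimilarityGraph, t: float) -> SimilarityGraph:
    """Binarize at *t* (closed rule: edge iff icc >= t) and measure reachability.

    Reachability is the fraction of ordered node pairs joined by a path;
    it equals 1 exactly when the graph is connected, and is
    non-increasing in *t*.
    """
    if not np.isfinite(t):
        if t == -np.inf:
            pass  # complete graph below
        else:
            raise ValueError("threshold must be finite or -inf")
    icc = graph.icc_matrix
    with np.errstate(invalid="ignore"):
        adjacency = (icc >= t).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    n_comp, labels = connected_components(adjacency, directed=False)
    sizes = np.bincount(labels)
    P = graph.n
    reach = float((sizes * (sizes - 1)).sum() / (P * (P - 1))) if P > 1 else 1.0
    return SimilarityGraph(ids=list(graph.ids), icc_matrix=icc, threshold=float(t),
                           adjacency=adjacency, reachability=reach)


def to_networkx(graph: SimilarityGraph) -> nx.Graph:
    """Thresholded graph as a networkx Graph with icc edge weights."""
    if graph.adjacency is None:
        raise ValueError("apply a threshold first")
    g = nx.Graph(threshold=graph.threshold)
    g.add_nodes_from(graph.ids)
    ii, jj = np.where(np.triu(graph.adjacency, 1))
    for i, j in zip(ii, jj):
        g.add_edge(graph.ids[i], graph.ids[j], icc=float(graph.icc_matrix[i, j]))
    return g


def write_edge_list(graph: SimilarityGraph, path: str | Path) -> None:
    """Undirected edge list CSV: id_i, id_j, icc."""
    g = to_networkx(graph)
    with open(path, "w") as fh:
        fh.write("id_i,id_j,icc\n")
        for a, b, d in g.edges(data=True):
            fh.write(f"{a},{b},{d['icc']:.6f}\n")


def write_graphml(graph: SimilarityGraph, path: str | Path) -> None:
    """GraphML export of the thresholded graph (Gephi-compatible)."""
    nx.write_graphml(to_networkx(graph), path)
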