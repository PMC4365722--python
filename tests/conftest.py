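"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cogtypology.cohort import RAW_COLUMNS, CohortTable
from cogtypology.simulate import default_spec, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_participant(pid: str = "p0", **overrides) -> dict:
    """A complete, healthy raw-participant row; override any field."""
    row = {
        "id": pid,
        "age_group": "young",
        "age_years": 22.0,
        "fluency_s": 18,
        "fluency_f": 14,
        "fluency_professions": 20,
        "fluency_animals": 24,
        "digit_span_forward": 7,
        "digit_span_backward": 5,
        "tmt_a_seconds": 30.0,
        "tmt_b_seconds": 66.0,
        "recall_block_1": 6,
        "recall_block_2": 8,
        "recall_block_3": 10,
        "recall_block_4": 11,
        "recall_block_5": 12,
        "delayed_recall": 10,
        "recognition": 15,
        "rt_median_ms": 280.0,
        "mmse": 29,
        "hads_anxiety": 3,
        "hads_depression": 2,
        "iq_crystallized": 105.0,
        "iq_fluid": 110.0,
        "digit_symbol": 80,
        "education_level": 3,
    }
    row.update(overrides)
    return row


def make_cohort(rows: list[dict]) -> CohortTable:
    return CohortTable(pd.DataFrame(rows, columns=list(RAW_COLUMNS)))


@pytest.fixture(scope="session")
def default_cohort():
    """The default six-profile synthetic cohort at seed 0 (155 participants)."""
    return generate(default_spec(seed=0))


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; never call package internals)

def icc_a1_oracle(x, y) -> float:
    """ICC(A,1) via the generic two-way ANOVA cell decomposition.

    Treats the data as an n x k table and computes all sums of squares by
    explicit loops over cells, independently of the package's formulas.
    """
    table = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = table.shape
    grand = table.mean()
    ss_rows = sum(k * (table[i, :].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((table[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


def connectivity_threshold_oracle(icc: np.ndarray) -> float:
    """Brute-force scan over sorted unique off-diagonal values."""
    from scipy.sparse.csgraph import connected_components

    P = icc.shape[0]
    values = sorted({icc[i, j] for i in range(P) for j in range(P) if i != j}, reverse=True)
    for t in values:
        adj = (icc >= t).astype(int)
        np.fill_diagonal(adj, 0)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1:
            return t
    raise AssertionError("complete value scan never connected the graph")


def set_partitions(items: list):
    """All set partitions of *items* (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1:]
        yield [[first]] + partition


def modularity_oracle(adj: np.ndarray, blocks: list[list[int]]) -> float:
    """Q from its definition, summed edge by edge."""
    k = adj.sum(axis=1)
    m = k.sum() / 2.0
    label = {}
    for c, block in enumerate(blocks):
        for node in block:
            label[node] = c
    q = 0.0
    P = adj.shape[0]
    for i in range(P):
        for j in range(P):
            if label[i] == label[j]:
                q += adj[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def max_modularity_oracle(adj: np.ndarray) -> float:
    """Exhaustive-search maximum Q over every partition (P <= ~9)."""
    best = -np.inf
    for partition in set_partitions(list(range(adj.shape[0]))):
        best = max(best, modularity_oracle(adj, partition))
    return best


def confusion_metrics_oracle(y_true, y_pred, classes) -> dict:
    """Per-class sensitivity/specificity by direct pair counting (percent)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {}
    for cls in classes:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        tn = int(np.sum((y_true != cls) & (y_pred != cls)))
        size = int(np.sum(y_true == cls))
        others = len(y_true) - size
        out[cls] = {
            "sensitivity": 100.0 * tp / size if size else float("nan"),
            "specificity": 100.0 * tn / others if others else float("nan"),
        }
    out["accuracy"] = 100.0 * float(np.mean(y_true == y_pred))
    return out


def anova_oracle(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way F from the raw sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ssb / df_b) / (ssw / df_w), df_b, df_w


def chi_square_oracle(table: np.ndarray) -> tuple[float, int]:
    """Pearson X^2 from the definitional double sum."""
    table = np.asarray(table, float)
    total = table.sum()
    x2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i, :].sum() * table[:, j].sum() / total
            x2 += (table[i, j] - expected) ** 2 / expected
    return x2, (table.shape[0] - 1) * (table.shape[1] - 1)


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Random Erdos-Renyi adjacency, resampled until connected."""
    from scipy.sparse.csgraph import connected_components

    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1).astype(int)
        adj = adj + adj.T
        if adj.sum() == 0:
            continue
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1:
            return adj
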