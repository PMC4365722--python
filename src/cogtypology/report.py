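"""Subgroup profile summaries and covariate statistics.

After communities are detected, two reporting questions remain: what
does each subgroup's cognitive profile look like, and do background
covariates that never entered the clustering (MMSE, HADS, IQ estimates,
digit-symbol coding, education attainment) differ between subgroups?

Profiles are five-number summaries (min, Q1, median, Q3, max, linear
interpolation quartiles) of the oriented z-scores per community, plus
young/old counts. Continuous covariates get a one-way omnibus ANOVA and
a pairwise post-hoc table (Welch t with Holm adjustment by default,
Tukey HSD optional); education level, an ordered categorical, gets a
Pearson chi-square on the per-pair 2 x L contingency table.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CompoundMatrix

__all__ = [
    "ProfileSummary",
    "summarize_profiles",
    "anova_oneway",
    "pairwise_posthoc",
    "chi_square_education",
    "covariate_tests",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES: tuple[str, ...] = (
    "mmse",
    "hads_anxiety",
    "hads_depression",
    "iq_crystallized",
    "iq_fluid",
    "digit_symbol",
)


@dataclasses.dataclass
class ProfileSummary:
    """Per-community cognitive profile: age mix and boxplot statistics."""

    community: int
    n_young: int
    n_old: int
    stats: pd.DataFrame  # index: score (sorted by median, ascending); cols: min,q1,median,q3,max

    @property
    def size(self) -> int:
        return self.n_young + self.n_old


def summarize_profiles(
    scores: CompoundMatrix,
    labels: Sequence[int],
    age_groups: Sequence[str] | None = None,
) -> list[ProfileSummary]:
    """Five-number summary of oriented z-scores per community per score.

    Scores are ordered by increasing median within each community, the
    way subgroup profile boxplots are conventionally drawn. *age_groups*
    ("young"/"old" per participant, cohort order) feeds the young/old
    counts; it is metadata only and never entered the clustering.
    """
    labels = np.asarray(labels)
    if len(labels) != len(scores.ids):
        raise ValueError("labels must cover every participant")
    if age_groups is None:
        age = np.array(["young"] * len(labels))
    else:
        age = np.asarray(age_groups)
    out = []
    for community in np.unique(labels):
        mask = labels == community
        if not mask.any():
            raise RuntimeError(f"community {community} is empty")  # impossible by construction
        block = scores.scores[mask]
        q = np.quantile(block, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)  # linear interpolation
        stats_df = pd.DataFrame(
            q.T, index=list(scores.score_names),
            columns=["min", "q1", "median", "q3", "max"],
        ).sort_values("median")
        out.append(ProfileSummary(
            community=int(community),
            n_young=int((age[mask] == "young").sum()),
            n_old=int((age[mask] == "old").sum()),
            stats=stats_df,
        ))
    return out


def anova_oneway(values: Sequence[float], group_labels: Sequence) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    names = np.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    n = len(values)
    if n <= len(names):
        raise ValueError("need more observations than groups")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for name in names:
        v = values[groups == name]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = len(names) - 1
    df_w = n - len(names)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("all observations identical; F undefined")
    ms_w = ss_within / df_w
    if ms_w == 0:
        raise ValueError("zero within-group variance; F undefined")
    f = (ss_between / df_b) / ms_w
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def pairwise_posthoc(
    values: Sequence[float],
    group_labels: Sequence,
    method: str = "welch-holm",
) -> pd.DataFrame:
    """All pairwise group comparisons with multiplicity-adjusted p-values.

    Returns one row per (row_group, col_group) pair with the sign of the
    mean difference (row minus column: +1/0/-1), the raw p and the
    adjusted p. ``welch-holm`` (default) uses Welch two-sample t tests
    with Holm step-down adjustment; ``tukey`` uses Tukey HSD.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    names = list(np.unique(groups))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*[values[groups == g] for g in names])
        for (a, b) in pairs:
            i, j = names.index(a), names.index(b)
            diff = values[groups == a].mean() - values[groups == b].mean()
            rows.append({"row": a, "col": b, "sign": int(np.sign(round(diff, 12))),
                         "mean_diff": diff, "p_raw": float(res.pvalue[i, j]),
                         "p_adj": float(res.pvalue[i, j])})
        return pd.DataFrame(rows)
    if method != "welch-holm":
        raise ValueError(f"unknown post-hoc method {method!r}")

    raw_p = []
    kept_pairs = []
    for a, b in pairs:
        va, vb = values[groups == a], values[groups == b]
        if len(va) == 1 and len(vb) == 1:
            warnings.warn(f"pair ({a}, {b}) has n=1 in both groups; skipped")
            continue
        diff = va.mean() - vb.mean()
        if va.std() == 0 and vb.std() == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        raw_p.append(p)
        kept_pairs.append((a, b, diff))
    adjusted = _holm(np.array(raw_p)) if raw_p else np.array([])
    for (a, b, diff), p, padj in zip(kept_pairs, raw_p, adjusted):
        rows.append({"row": a, "col": b, "sign": int(np.sign(round(diff, 12))),
                     "mean_diff": diff, "p_raw": p, "p_adj": float(padj)})
    return pd.DataFrame(rows)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def chi_square_education(counts_table: np.ndarray) -> tuple[float, int, float, bool]:
    """Pearson chi-square on a 2 x L education contingency table.

    All-zero columns (education levels unused by both groups) are
    dropped, reducing the degrees of freedom. Returns
    ``(X2, df, p, low_expected)`` where *low_expected* flags any expected
    cell count below 5. No continuity correction is applied.
    """
    table = np.asarray(counts_table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] > 4:
        raise ValueError("expected a 2 x L table with L <= 4")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 non-empty education levels; chi-square undefined")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("a group has zero total count; chi-square undefined")
    x2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return float(x2), int(df), float(p), bool((expected < 5).any())


def covariate_tests(
    cohort_data: pd.DataFrame,
    labels: Sequence[int],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    posthoc_method: str = "welch-holm",
) -> dict:
    """Omnibus ANOVA + post-hoc per covariate and pairwise education chi-squares.

    *cohort_data* is the included cohort's raw table (cohort row order
    must match *labels*). Returns a JSON-serializable dict.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort_data):
        raise ValueError("labels must cover every cohort row")
    out: dict = {"anova": {}, "education_chi_square": []}
    for cov in covariates:
        values = cohort_data[cov].to_numpy(dtype=float)
        f, df_b, df_w, p = anova_oneway(values, labels)
        table = pairwise_posthoc(values, labels, method=posthoc_method)
        out["anova"][cov] = {
            "F": f, "df": [df_b, df_w], "p": p,
            "pairwise": table.to_dict(orient="records"),
        }
    edu = cohort_data["education_level"].to_numpy(dtype=int)
    for a, b in itertools.combinations(np.unique(labels).tolist(), 2):
        counts = np.array([
            [(edu[labels == g] == level).sum() for level in (1, 2, 3, 4)]
            for g in (a, b)
        ])
        try:
            x2, df, p, low = chi_square_education(counts)
        except ValueError as exc:
            out["education_chi_square"].append({"pair": [int(a), int(b)], "error": str(exc)})
            continue
        out["education_chi_square"].append(
            {"pair": [int(a), int(b)], "X2": x2, "df": df, "p": p, "low_expected": low})
    return out
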