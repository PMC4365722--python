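"""Cohort schema, I/O, inclusion filtering and compound cognitive scores.

A cohort is a table with one row per participant holding raw
neuropsychological test scores (verbal fluency word counts, digit spans,
trail-making completion times, 15-words recall counts, median simple
reaction time) plus screening and background covariates (MMSE, HADS
anxiety/depression, crystallized and fluid IQ estimates, digit-symbol
coding, education attainment level 1-4).

Eight compound scores summarize the battery:

=====================  ==================================================
phonemic_fluency       mean of the "S" and "F" letter-fluency counts
semantic_fluency       mean of the professions and animals counts
working_memory_span    mean of digit span forward and backward
tmt_a                  trail-making A completion time (s)
tmt_b_over_a           trail-making B time divided by A time
immediate_recall       sum of the five immediate-recall blocks
delayed_recall         delayed recall count
response_speed         median reaction time (ms)
=====================  ==================================================

The recognition score of the 15-words test is deliberately never used: it
shows too little variability across healthy adults to inform a typology.
Compound scores are z-transformed over the whole included cohort and the
three time-based scores are sign-flipped so that higher always means
better performance.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortError",
    "SchemaError",
    "ZeroVarianceError",
    "CohortTable",
    "CompoundMatrix",
    "COMPOUND_SCORE_NAMES",
    "TIME_BASED_SCORES",
    "RAW_COLUMNS",
    "COMPOUND_FIELDS",
    "read_cohort",
    "write_cohort",
    "apply_inclusion",
    "compound_scores",
    "standardize_and_orient",
]


class CohortError(ValueError):
    """Invalid cohort content (duplicate ids, empty result, bad values)."""


class SchemaError(CohortError):
    """Cohort file does not match the expected column schema."""


class ZeroVarianceError(CohortError):
    """A compound score is constant and cannot be z-transformed."""


#: Ordered labels of the eight compound scores.
COMPOUND_SCORE_NAMES: tuple[str, ...] = (
    "phonemic_fluency",
    "semantic_fluency",
    "working_memory_span",
    "tmt_a",
    "tmt_b_over_a",
    "immediate_recall",
    "delayed_recall",
    "response_speed",
)

#: Scores where a lower raw value means better performance; these columns
#: are multiplied by -1 after the z-transform.
TIME_BASED_SCORES: tuple[str, ...] = ("tmt_a", "tmt_b_over_a", "response_speed")

RECALL_BLOCK_COLUMNS: tuple[str, ...] = tuple(f"recall_block_{i}" for i in range(1, 6))

#: Full raw-cohort column schema, in canonical order.
RAW_COLUMNS: tuple[str, ...] = (
    "id",
    "age_group",
    "age_years",
    "fluency_s",
    "fluency_f",
    "fluency_professions",
    "fluency_animals",
    "digit_span_forward",
    "digit_span_backward",
    "tmt_a_seconds",
    "tmt_b_seconds",
    *RECALL_BLOCK_COLUMNS,
    "delayed_recall",
    "recognition",
    "rt_median_ms",
    "mmse",
    "hads_anxiety",
    "hads_depression",
    "iq_crystallized",
    "iq_fluid",
    "digit_symbol",
    "education_level",
)

#: Raw fields that feed the compound scores; a participant missing any of
#: these did not complete the battery and is excluded.
COMPOUND_FIELDS: tuple[str, ...] = (
    "fluency_s",
    "fluency_f",
    "fluency_professions",
    "fluency_animals",
    "digit_span_forward",
    "digit_span_backward",
    "tmt_a_seconds",
    "tmt_b_seconds",
    *RECALL_BLOCK_COLUMNS,
    "delayed_recall",
    "rt_median_ms",
)

_AGE_GROUPS = frozenset({"young", "old"})


@dataclasses.dataclass
class CohortTable:
    """Raw cohort: one row per participant, stable order, unique ids.

    Parameters
    ----------
    data
        DataFrame with the :data:`RAW_COLUMNS` schema (default integer
        index; participant identity lives in the ``id`` column).
    provenance
        Free-text description of where the rows came from.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in RAW_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")
        unknown = [c for c in self.data.columns if c not in RAW_COLUMNS]
        if unknown:
            raise SchemaError(f"cohort table has unknown columns: {unknown}")
        ids = self.data["id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortError(f"duplicate participant id(s): {sorted(set(dup))}")
        bad_age = set(self.data["age_group"].dropna()) - _AGE_GROUPS
        if bad_age:
            raise CohortError(f"age_group values outside {{young, old}}: {sorted(bad_age)}")
        edu = self.data["education_level"].dropna()
        if len(edu) and not edu.isin([1, 2, 3, 4]).all():
            raise CohortError("education_level values must be in {1, 2, 3, 4}")
        # normalise column order without copying data
        self.data = self.data.loc[:, list(RAW_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.data["id"]]

    def equals(self, other: "CohortTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(x.astype(float), y.astype(float), equal_nan=True):
                    return False
            elif not (x.astype(object).where(x.notna(), "\0")
                      == y.astype(object).where(y.notna(), "\0")).all():
                return False
        return True


@dataclasses.dataclass
class CompoundMatrix:
    """Participants x 8 matrix of oriented z-scored compound scores."""

    ids: list[str]
    scores: np.ndarray
    score_names: tuple[str, ...] = COMPOUND_SCORE_NAMES
    orientation_applied: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.score_names):
            raise CohortError(
                f"scores must be (n, {len(self.score_names)}); got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.ids):
            raise CohortError("ids and score rows disagree in length")
        if np.isnan(self.scores).any():
            raise CohortError("compound matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=pd.Index(self.ids, name="id"),
                            columns=list(self.score_names))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".tab")) else "csv"
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_cohort(path: str | Path, dialect: str | None = None) -> CohortTable:
    """Read a cohort CSV/TSV file into a :class:`CohortTable`.

    Missing cells are kept as missing (NaN), never coerced to zero.
    Raises :class:`SchemaError` for unknown/missing columns and
    :class:`CohortError` for malformed rows or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_dialect_sep(path, dialect), dtype={"id": str})
    except pd.errors.ParserError as exc:  # pandas names the offending row
        raise CohortError(f"malformed cohort file {path.name}: {exc}") from exc
    return CohortTable(df, provenance=str(path))


def write_cohort(table: CohortTable, path: str | Path, dialect: str | None = None) -> None:
    """Write a cohort table in the CSV/TSV dialect inferred from *path*."""
    table.data.to_csv(path, sep=_dialect_sep(path, dialect), index=False)


def apply_inclusion(
    table: CohortTable,
    mmse_min_exclusive: int = 26,
    hads_max_exclusive: int = 16,
    mmse_inclusive: bool = False,
    hads_inclusive: bool = False,
) -> tuple[CohortTable, list[dict]]:
    """Apply screening criteria and drop incomplete participants.

    Default semantics are strict ("scored above 26 on the MMSE and below
    16 on each of the HADS subscales"): retained participants satisfy
    ``mmse > 26`` and both HADS subscales ``< 16``. The ``*_inclusive``
    flags relax the boundaries to >= / <=.

    Returns the filtered table plus an exclusion log: one dict per
    dropped participant with ``id`` and ``reason``. The filter is
    idempotent.
    """
    df = table.data
    for col in ("mmse", "hads_anxiety", "hads_depression"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "id"].tolist()
            raise CohortError(f"screening score {col!r} missing for participant(s) {bad}")

    mmse_ok = df["mmse"] >= mmse_min_exclusive if mmse_inclusive else df["mmse"] > mmse_min_exclusive
    if hads_inclusive:
        hads_ok = (df["hads_anxiety"] <= hads_max_exclusive) & (df["hads_depression"] <= hads_max_exclusive)
    else:
        hads_ok = (df["hads_anxiety"] < hads_max_exclusive) & (df["hads_depression"] < hads_max_exclusive)
    complete = df[list(COMPOUND_FIELDS)].notna().all(axis=1)

    log: list[dict] = []
    for _, row in df.iterrows():
        reasons = []
        if not (row["mmse"] >= mmse_min_exclusive if mmse_inclusive else row["mmse"] > mmse_min_exclusive):
            reasons.append(f"mmse {row['mmse']} fails screening threshold")
        anx_ok = row["hads_anxiety"] <= hads_max_exclusive if hads_inclusive else row["hads_anxiety"] < hads_max_exclusive
        dep_ok = row["hads_depression"] <= hads_max_exclusive if hads_inclusive else row["hads_depression"] < hads_max_exclusive
        if not (anx_ok and dep_ok):
            reasons.append("HADS subscale fails screening threshold")
        if row[list(COMPOUND_FIELDS)].isna().any():
            reasons.append("did not complete all neuropsychological tests")
        if reasons:
            log.append({"id": str(row["id"]), "reason": "; ".join(reasons)})

    keep = mmse_ok & hads_ok & complete
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise CohortError("inclusion criteria excluded every participant; nothing to cluster")
    for entry in log:
        logger.info("excluded participant %s: %s", entry["id"], entry["reason"])
    return CohortTable(out, provenance=table.provenance), log


def compound_scores(table: CohortTable) -> pd.DataFrame:
    """Compute the raw (unstandardized) participants x 8 compound matrix.

    Returns a DataFrame indexed by participant id with
    :data:`COMPOUND_SCORE_NAMES` columns, in cohort row order. The
    recognition score is never used.
    """
    df = table.data
    incomplete = df[list(COMPOUND_FIELDS)].isna().any(axis=1)
    if incomplete.any():
        bad = df.loc[incomplete, "id"].tolist()
        raise CohortError(f"missing compound-relevant scores for participant(s) {bad}")
    if (df["tmt_a_seconds"] == 0).any():
        bad = df.loc[df["tmt_a_seconds"] == 0, "id"].tolist()
        raise CohortError(f"tmt_a_seconds is zero for {bad}; B/A ratio undefined")

    out = pd.DataFrame(index=pd.Index(df["id"].astype(str), name="id"))
    out["phonemic_fluency"] = ((df["fluency_s"] + df["fluency_f"]) / 2.0).to_numpy()
    out["semantic_fluency"] = ((df["fluency_professions"] + df["fluency_animals"]) / 2.0).to_numpy()
    out["working_memory_span"] = ((df["digit_span_forward"] + df["digit_span_backward"]) / 2.0).to_numpy()
    out["tmt_a"] = df["tmt_a_seconds"].to_numpy(dtype=float)
    out["tmt_b_over_a"] = (df["tmt_b_seconds"] / df["tmt_a_seconds"]).to_numpy()
    out["immediate_recall"] = df[list(RECALL_BLOCK_COLUMNS)].sum(axis=1).to_numpy(dtype=float)
    out["delayed_recall"] = df["delayed_recall"].to_numpy(dtype=float)
    out["response_speed"] = df["rt_median_ms"].to_numpy(dtype=float)
    return out


def standardize_and_orient(
    raw_matrix: pd.DataFrame,
    ddof: int = 1,
    orient: bool = True,
    time_based: Iterable[str] = TIME_BASED_SCORES,
) -> CompoundMatrix:
    """z-transform each compound score and flip time-based columns.

    z-scores use the sample standard deviation (``ddof=1``) over all
    included participants, pooled over age groups. Columns listed in
    *time_based* (trail-making A, B/A ratio, reaction time) are then
    multiplied by -1 so that higher oriented scores always mean better
    performance.
    """
    if list(raw_matrix.columns) != list(COMPOUND_SCORE_NAMES):
        raise SchemaError(
            f"expected compound columns {list(COMPOUND_SCORE_NAMES)}, got {list(raw_matrix.columns)}"
        )
    if len(raw_matrix) < 2:
        raise CohortError("need at least 2 participants to standardize")
    values = raw_matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=ddof)
    for name, s in zip(COMPOUND_SCORE_NAMES, sd):
        if s == 0 or not np.isfinite(s):
            raise ZeroVarianceError(f"compound score {name!r} has zero variance")
    z = (values - values.mean(axis=0)) / sd
    if orient:
        flip = [i for i, name in enumerate(COMPOUND_SCORE_NAMES) if name in set(time_based)]
        z[:, flip] *= -1.0
    return CompoundMatrix(
        ids=[str(i) for i in raw_matrix.index],
        scores=z,
        orientation_applied=bool(orient),
    )
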