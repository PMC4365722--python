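"""Synthetic cohorts with planted subgroup structure.

Real cohorts of this kind are rarely shareable, so every downstream
stage is exercised on generated cohorts instead. A cohort spec
plants a set of latent subgroups, each with a mean profile over the eight
compound scores expressed in population z-units (oriented: higher =
better), isotropic Gaussian within-group noise, and subgroup-linked
covariates (MMSE, HADS, IQ estimates, digit-symbol, education level,
age-group composition).

The default spec emulates a six-subgroup typology of 155
young and older adults:

* S1 (young): below-average verbal fluency, above average elsewhere.
* S2 (mostly young): strong executive/memory scores, weaker fluency,
  span and reaction time.
* S3 (mixed age): slower than average, above average on everything else.
* S4 (mostly old): faster than average but below average elsewhere.
* S5 (old, small): globally decreased, worst on the trail-making B/A
  executive index.
* S6 (mostly old): weak immediate/delayed recall and reaction time,
  average-or-better elsewhere.

Generation draws oriented z-profiles per member, maps them to raw score
units via per-score anchors, and inverts the compound definitions to emit
plausible raw test fields. The inversion preserves the compound values
exactly for integer scores (fluency and span pairs are split around an
integer total; the five recall blocks sum exactly), so a profile with
``within_sd = 0`` produces members with identical compound profiles.
Covariates are generated consistently with the screening criteria (MMSE
in 27-30, HADS in 0-15): the planted cohort represents the included
population, the way demographics tables for included cohorts do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import COMPOUND_SCORE_NAMES, RAW_COLUMNS, CohortTable

logger = logging.getLogger(__name__)

__all__ = ["ProfileSpec", "CohortSpec", "default_spec", "generate"]

#: Covariates that take per-profile (mean, sd) pairs.
COVARIATE_NAMES: tuple[str, ...] = (
    "mmse",
    "hads_anxiety",
    "hads_depression",
    "iq_crystallized",
    "iq_fluid",
    "digit_symbol",
)

#: Raw-unit anchors (mean, sd) mapping oriented z-units to raw scores.
#: Time-based scores map with a negated slope (better = faster = lower raw).
DEFAULT_ANCHORS: dict[str, tuple[float, float]] = {
    "phonemic_fluency": (16.0, 4.0),      # words / 60 s
    "semantic_fluency": (22.0, 5.0),      # words / 60 s
    "working_memory_span": (6.0, 1.0),    # digits
    "tmt_a": (35.0, 10.0),                # seconds
    "tmt_b_over_a": (2.2, 0.5),           # ratio
    "immediate_recall": (45.0, 8.0),      # words over 5 blocks (max 75)
    "delayed_recall": (10.0, 2.5),        # words (max 15)
    "response_speed": (300.0, 50.0),      # ms
}

_TIME_BASED = {"tmt_a", "tmt_b_over_a", "response_speed"}


@dataclasses.dataclass
class ProfileSpec:
    """One planted subgroup: size, mean z-profile, noise and covariates."""

    label: str
    n_members: int
    mean_profile: Sequence[float]
    within_sd: float = 0.6
    young_fraction: float = 0.5
    covariate_means: Mapping[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    education_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError(f"profile {self.label!r}: n_members must be >= 1")
        if self.within_sd < 0:
            raise ValueError(f"profile {self.label!r}: within_sd must be >= 0")
        self.mean_profile = tuple(float(v) for v in self.mean_profile)
        if len(self.mean_profile) != len(COMPOUND_SCORE_NAMES):
            raise ValueError(f"profile {self.label!r}: mean_profile must have 8 entries")
        if not 0.0 <= self.young_fraction <= 1.0:
            raise ValueError(f"profile {self.label!r}: young_fraction must be in [0, 1]")
        self.education_probs = tuple(float(p) for p in self.education_probs)
        if len(self.education_probs) != 4 or abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError(f"profile {self.label!r}: education_probs must be 4 values summing to 1")


@dataclasses.dataclass
class CohortSpec:
    """A full synthetic-cohort specification; `generate` is pure in it."""

    profiles: list[ProfileSpec]
    seed: int = 0
    raw_scale_anchors: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )

    def __post_init__(self) -> None:
        total = sum(p.n_members for p in self.profiles)
        if total < 2 * len(self.profiles):
            raise ValueError("total cohort size must be at least twice the number of profiles")
        missing = set(COMPOUND_SCORE_NAMES) - set(self.raw_scale_anchors)
        if missing:
            raise ValueError(f"raw_scale_anchors missing scores: {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "raw_scale_anchors": {k: list(v) for k, v in self.raw_scale_anchors.items()},
            "profiles": [
                {
                    "label": p.label,
                    "n_members": p.n_members,
                    "mean_profile": list(p.mean_profile),
                    "within_sd": p.within_sd,
                    "young_fraction": p.young_fraction,
                    "covariate_means": {k: list(v) for k, v in p.covariate_means.items()},
                    "education_probs": list(p.education_probs),
                }
                for p in self.profiles
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        payload = json.loads(Path(path).read_text())
        profiles = [
            ProfileSpec(
                label=p["label"],
                n_members=p["n_members"],
                mean_profile=p["mean_profile"],
                within_sd=p.get("within_sd", 0.6),
                young_fraction=p.get("young_fraction", 0.5),
                covariate_means={k: tuple(v) for k, v in p.get("covariate_means", {}).items()},
                education_probs=p.get("education_probs", (0.25, 0.25, 0.25, 0.25)),
            )
            for p in payload["profiles"]
        ]
        anchors = {k: tuple(v) for k, v in payload.get(
            "raw_scale_anchors", {k: list(v) for k, v in DEFAULT_ANCHORS.items()}).items()}
        return cls(profiles=profiles, seed=payload.get("seed", 0), raw_scale_anchors=anchors)


# Subgroup mean patterns in oriented z-units at the default separation (2.0).
# Order: phonemic, semantic, span, tmt_a, tmt_b/a, imm. recall, del. recall, RT.
# Sign structure encodes each subgroup's verbal profile description; the
# magnitudes were calibrated once so that (a) profiles keep substantial
# within-profile score variance (pairwise ICC between members of one subgroup
# stays clearly above between-subgroup ICC under the default noise) and
# (b) the planted partition is recoverable by the full pipeline.
_BASE_PATTERNS: dict[str, tuple[float, ...]] = {
    "S1": (-1.9, -1.9, 0.75, 0.75, 0.75, 0.75, 0.75, 0.75),
    "S2": (-1.3, 0.0, -1.3, 1.3, 1.3, 1.3, 1.3, -1.3),
    "S3": (0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, -2.5),
    "S4": (-1.2, -1.2, -1.2, -0.1, -0.1, -1.2, -1.2, 2.5),
    "S5": (-0.1, -0.1, -0.1, -2.0, -3.6, -0.6, -0.6, -0.3),
    "S6": (0.8, 0.8, 0.8, 0.8, 0.8, -1.8, -1.8, -1.1),
}

_SIZES = {"S1": 23, "S2": 39, "S3": 31, "S4": 26, "S5": 11, "S6": 25}
_YOUNG = {"S1": 23, "S2": 35, "S3": 16, "S4": 2, "S5": 1, "S6": 2}

# Default per-subgroup demographics: (mean, sd) per covariate.
_COVARIATES: dict[str, dict[str, tuple[float, float]]] = {
    "S1": {"mmse": (29.4, 0.7), "hads_anxiety": (3.8, 1.7), "hads_depression": (1.4, 1.6),
           "iq_crystallized": (103.7, 5.6), "iq_fluid": (113.0, 12.6), "digit_symbol": (86.0, 12.7)},
    "S2": {"mmse": (29.5, 0.6), "hads_anxiety": (3.2, 2.2), "hads_depression": (1.8, 1.9),
           "iq_crystallized": (102.3, 4.9), "iq_fluid": (111.2, 10.0), "digit_symbol": (83.0, 15.1)},
    "S3": {"mmse": (29.6, 0.6), "hads_anxiety": (3.9, 2.8), "hads_depression": (1.5, 1.6),
           "iq_crystallized": (111.0, 8.7), "iq_fluid": (111.6, 9.1), "digit_symbol": (79.5, 14.0)},
    "S4": {"mmse": (28.4, 1.1), "hads_anxiety": (3.7, 2.2), "hads_depression": (2.3, 2.6),
           "iq_crystallized": (105.2, 10.4), "iq_fluid": (106.5, 8.6), "digit_symbol": (60.5, 8.3)},
    "S5": {"mmse": (28.1, 1.2), "hads_anxiety": (4.6, 2.7), "hads_depression": (3.0, 2.9),
           "iq_crystallized": (96.5, 7.8), "iq_fluid": (97.3, 9.3), "digit_symbol": (56.2, 13.5)},
    "S6": {"mmse": (28.5, 1.1), "hads_anxiety": (3.2, 2.9), "hads_depression": (1.6, 1.2),
           "iq_crystallized": (114.0, 9.3), "iq_fluid": (111.0, 9.2), "digit_symbol": (72.6, 13.3)},
}

# Default education attainment counts (levels 1-4) per subgroup.
_EDUCATION_COUNTS = {
    "S1": (0, 0, 18, 5),
    "S2": (0, 0, 24, 15),
    "S3": (0, 0, 11, 20),
    "S4": (0, 7, 6, 13),
    "S5": (1, 3, 5, 2),
    "S6": (0, 0, 10, 15),
}


def default_spec(separation: float = 2.0, within_sd: float = 0.6, seed: int = 0) -> CohortSpec:
    """Six-profile default cohort spec (sizes 23/39/31/26/11/25, n = 155).

    *separation* scales the base patterns so that the minimum pairwise
    distance between mean profiles is about *separation* z-units (2.0 by
    default). Covariate (mean, sd) pairs and education distributions are
    realistic per-subgroup demographic defaults.
    """
    scale = separation / 2.0
    profiles = []
    for label in ("S1", "S2", "S3", "S4", "S5", "S6"):
        counts = _EDUCATION_COUNTS[label]
        profiles.append(
            ProfileSpec(
                label=label,
                n_members=_SIZES[label],
                mean_profile=tuple(scale * v for v in _BASE_PATTERNS[label]),
                within_sd=within_sd,
                young_fraction=_YOUNG[label] / _SIZES[label],
                covariate_means=dict(_COVARIATES[label]),
                education_probs=tuple(c / sum(counts) for c in counts),
            )
        )
    return CohortSpec(profiles=profiles, seed=seed)


def _split_pair(total: int, rng: np.random.Generator, spread: int, ordered: bool = False) -> tuple[int, int]:
    """Split integer *total* into two nonnegative parts with mean total/2."""
    half = total // 2
    delta = int(rng.integers(-spread, spread + 1))
    if ordered:
        delta = abs(delta)
    first = total - half + delta  # gets the odd remainder
    second = half - delta
    if second < 0:
        first, second = total, 0
    if first < 0:
        first, second = 0, total
    return first, second


def _recall_blocks(total: int, rng: np.random.Generator) -> list[int]:
    """Split *total* (0..75) into 5 blocks of at most 15, rising with practice."""
    base = total // 5
    rem = total - 5 * base
    blocks = [base] * 5
    for j in range(rem):  # remainder goes to the later blocks (learning effect)
        blocks[4 - j] += 1
    # jitter that conserves the sum and the 0..15 range
    for _ in range(3):
        i, j = rng.integers(0, 5, size=2)
        if i < j and blocks[i] > 0 and blocks[j] < 15:
            blocks[i] -= 1
            blocks[j] += 1
    return blocks


def generate(spec: CohortSpec) -> tuple[CohortTable, pd.Series]:
    """Generate a cohort from *spec*; returns (table, hidden true labels).

    Fully determined by ``spec.seed``. Raw values that would fall outside
    their physical range (negative times or counts) are clipped and the
    clip count logged.
    """
    rng = np.random.default_rng(spec.seed)
    anchors = {k: (float(m), float(s)) for k, (m, s) in spec.raw_scale_anchors.items()}
    rows: list[dict] = []
    labels: list[str] = []
    n_clipped = 0

    def clip(value: float, lo: float, hi: float | None = None) -> float:
        nonlocal n_clipped
        clipped = max(value, lo) if hi is None else min(max(value, lo), hi)
        if clipped != value:
            n_clipped += 1
        return clipped

    idx = 0
    for profile in spec.profiles:
        mu = np.asarray(profile.mean_profile, dtype=float)
        n_young = int(round(profile.young_fraction * profile.n_members))
        for member in range(profile.n_members):
            z = rng.normal(mu, profile.within_sd)
            raw = {}
            for name, zv in zip(COMPOUND_SCORE_NAMES, z):
                m, s = anchors[name]
                raw[name] = m - zv * s if name in _TIME_BASED else m + zv * s

            row: dict = {"id": f"p{idx:03d}"}
            row["age_group"] = "young" if member < n_young else "old"
            row["age_years"] = round(float(rng.uniform(18, 26) if row["age_group"] == "young"
                                           else rng.uniform(59, 74)), 1)

            tot_phon = int(clip(round(2 * raw["phonemic_fluency"]), 0))
            row["fluency_s"], row["fluency_f"] = _split_pair(tot_phon, rng, spread=3)
            tot_sem = int(clip(round(2 * raw["semantic_fluency"]), 0))
            row["fluency_professions"], row["fluency_animals"] = _split_pair(tot_sem, rng, spread=4)
            tot_span = int(clip(round(2 * raw["working_memory_span"]), 0))
            # forward span is typically the larger of the two
            row["digit_span_forward"], row["digit_span_backward"] = _split_pair(
                tot_span, rng, spread=1, ordered=True)

            tmt_a = clip(raw["tmt_a"], 8.0)
            ratio = clip(raw["tmt_b_over_a"], 1.05)
            row["tmt_a_seconds"] = round(tmt_a, 1)
            row["tmt_b_seconds"] = round(row["tmt_a_seconds"] * ratio, 1)

            imm = int(clip(round(raw["immediate_recall"]), 0, 75))
            for k, b in enumerate(_recall_blocks(imm, rng), start=1):
                row[f"recall_block_{k}"] = b
            row["delayed_recall"] = int(clip(round(raw["delayed_recall"]), 0, 15))
            # recognition is near ceiling for healthy adults (and unused downstream)
            row["recognition"] = int(rng.choice([13, 14, 15], p=[0.1, 0.3, 0.6]))
            row["rt_median_ms"] = round(clip(raw["response_speed"], 150.0), 1)

            cov = profile.covariate_means
            row["mmse"] = int(clip(round(rng.normal(*cov.get("mmse", (29.0, 0.8)))), 27, 30))
            row["hads_anxiety"] = int(clip(round(rng.normal(*cov.get("hads_anxiety", (3.5, 2.0)))), 0, 15))
            row["hads_depression"] = int(clip(round(rng.normal(*cov.get("hads_depression", (2.0, 2.0)))), 0, 15))
            row["iq_crystallized"] = round(clip(rng.normal(*cov.get("iq_crystallized", (105.0, 8.0))), 55.0), 1)
            row["iq_fluid"] = round(clip(rng.normal(*cov.get("iq_fluid", (108.0, 10.0))), 55.0), 1)
            row["digit_symbol"] = int(clip(round(rng.normal(*cov.get("digit_symbol", (75.0, 13.0)))), 0))
            row["education_level"] = int(rng.choice([1, 2, 3, 4], p=profile.education_probs))

            rows.append(row)
            labels.append(profile.label)
            idx += 1

    if n_clipped:
        logger.info("clipped %d out-of-range raw values during generation", n_clipped)
    df = pd.DataFrame(rows, columns=list(RAW_COLUMNS))
    table = CohortTable(df, provenance=f"synthetic cohort (seed={spec.seed})")
    true_labels = pd.Series(labels, index=pd.Index(table.ids, name="id"), name="true_label")
    return table, true_labels
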