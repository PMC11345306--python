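"""Plausibility filtering, whole-day exclusion, run averaging, dog filter.

The upstream feature-extraction software occasionally produces implausible
values (e.g. 2 m step lengths from doubly-detected step frequencies). A
single implausible value discredits the whole recording session, so the
entire data series of that dog on that day — every feature, every run — is
excluded, not just the offending row.

Plausibility bounds by feature category (upper bound exclusive above,
lower bound inclusive: a value is implausible iff value > upper or
value <= lower), plus a global age cut-off:

====================  =======  =======
category               upper    lower
====================  =======  =======
energy                 200      0
step_length            0.6 m    0.1 m
withers                0.6 m    0.15 m
age (all categories)   450 d    —
====================  =======  =======

After filtering, the 1-3 runs of each examination day are averaged into a
single day value per feature, and dogs with fewer than ``min_days`` distinct
surviving measurement days (default 4) are dropped entirely. A dog's day
count uses distinct surviving dates across all features, not per-feature
counts: a feature missing on some days merely shortens that feature's
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CatalogueError

AGE_LIMIT_DAYS = 450

EXCLUSION_LOG_COLUMNS = ["dog_id", "age_days", "reason", "feature_id", "value"]


@dataclass(frozen=True)
class ExclusionBounds:
    """Category bounds: implausible iff value > upper or value <= lower."""

    upper: float
    lower: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(f"upper ({self.upper}) must exceed lower ({self.lower})")

    def violates(self, value: float) -> bool:
        return value > self.upper or value <= self.lower


DEFAULT_BOUNDS: dict[str, ExclusionBounds] = {
    "energy": ExclusionBounds(upper=200.0, lower=0.0),
    "step_length": ExclusionBounds(upper=0.6, lower=0.1),
    "withers": ExclusionBounds(upper=0.6, lower=0.15),
}


@dataclass(frozen=True)
class VisitSeries:
    """Day-averaged (age, value) trajectory of one feature for one dog."""

    dog_id: str
    feature_id: str
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.values):
            raise ValueError("ages and values must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")

    @property
    def n_days(self) -> int:
        return len(self.ages)


def flag_implausible(
    runs: pd.DataFrame,
    features: pd.DataFrame,
    bounds: dict[str, ExclusionBounds] | None = None,
    age_limit_days: int = AGE_LIMIT_DAYS,
) -> pd.DataFrame:
    """Flag runs violating their category's plausibility bounds or the age cut.

    Returns an exclusion log with one entry per offending run
    (columns ``EXCLUSION_LOG_COLUMNS``; ``reason`` is one of
    ``energy_bounds``, ``step_length_bounds``, ``withers_bounds``,
    ``age_bound``). Features of category "none" are never value-flagged but
    are still subject to the age cut. Raises :class:`CatalogueError` if a
    run references a feature id missing from the catalogue.
    """
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    known = set(features["feature_id"])
    unknown = set(runs["feature_id"]) - known
    if unknown:
        raise CatalogueError(f"run(s) reference unknown feature id(s): {sorted(unknown)}")

    category = runs["feature_id"].map(
        dict(zip(features["feature_id"], features["exclusion_category"]))
    )
    entries = []

    age_mask = runs["age_days"] > age_limit_days
    if age_mask.any():
        hit = runs.loc[age_mask]
        entries.append(
            pd.DataFrame(
                {
                    "dog_id": hit["dog_id"],
                    "age_days": hit["age_days"],
                    "reason": "age_bound",
                    "feature_id": hit["feature_id"],
                    "value": hit["value"],
                }
            )
        )

    for cat, b in bounds.items():
        mask = (category == cat) & ((runs["value"] > b.upper) | (runs["value"] <= b.lower))
        if mask.any():
            hit = runs.loc[mask]
            entries.append(
                pd.DataFrame(
                    {
                        "dog_id": hit["dog_id"],
                        "age_days": hit["age_days"],
                        "reason": f"{cat}_bounds",
                        "feature_id": hit["feature_id"],
                        "value": hit["value"],
                    }
                )
            )

    if not entries:
        return pd.DataFrame(columns=EXCLUSION_LOG_COLUMNS)
    log = pd.concat(entries, ignore_index=True)
    return log.sort_values(["dog_id", "age_days", "feature_id"]).reset_index(drop=True)


def drop_flagged_days(runs: pd.DataFrame, log: pd.DataFrame) -> pd.DataFrame:
    """Remove every run of a dog on a day that has any exclusion-log entry.

    The removal spans all features and all run indices of that dog-day; runs
    of other days and dogs are untouched.
    """
    if len(log) == 0:
        return runs.reset_index(drop=True)
    flagged = set(zip(log["dog_id"], log["age_days"]))
    keep = ~pd.Series(list(zip(runs["dog_id"], runs["age_days"])), index=runs.index).isin(
        flagged
    )
    return runs.loc[keep].reset_index(drop=True)


def average_runs_per_day(runs: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of the 1-3 run values per (dog, day, feature)."""
    out = (
        runs.groupby(["dog_id", "age_days", "feature_id"], as_index=False, sort=True)["value"]
        .mean()
    )
    return out


def filter_min_days(
    day_records: pd.DataFrame, min_days: int = 4
) -> tuple[pd.DataFrame, list[str]]:
    """Drop dogs with fewer than ``min_days`` distinct surviving days.

    Returns the surviving day records (sorted by dog, feature, age) and the
    sorted list of removed dog ids. The day count is the number of distinct
    ``age_days`` a dog retains across all features.
    """
    if len(day_records) == 0:
        return day_records.reset_index(drop=True), []
    counts = day_records.groupby("dog_id")["age_days"].nunique()
    removed = sorted(counts.index[counts < min_days])
    kept = day_records[~day_records["dog_id"].isin(removed)]
    kept = kept.sort_values(["dog_id", "feature_id", "age_days"]).reset_index(drop=True)
    return kept, removed


def iter_series(day_records: pd.DataFrame):
    """Yield one :class:`VisitSeries` per (dog, feature), ages ascending."""
    for (dog_id, feature_id), grp in day_records.groupby(
        ["dog_id", "feature_id"], sort=True
    ):
        grp = grp.sort_values("age_days")
        yield VisitSeries(
            dog_id=dog_id,
            feature_id=feature_id,
            ages=grp["age_days"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
        )


@dataclass
class PreprocessResult:
    """Everything the preprocessing stage produces, plus audit counts.

    ``counts`` satisfies the conservation identity:
    rows_in = rows_out + rows_on_excluded_days + rows_of_removed_dogs.
    """

    day_records: pd.DataFrame
    exclusions: pd.DataFrame
    removed_dogs: list[str]
    counts: dict = field(default_factory=dict)


def run_preprocessing(
    runs: pd.DataFrame,
    features: pd.DataFrame,
    bounds: dict[str, ExclusionBounds] | None = None,
    min_days: int = 4,
    age_limit_days: int = AGE_LIMIT_DAYS,
) -> PreprocessResult:
    """Full preprocessing: flag -> drop days -> average runs -> dog filter."""
    log = flag_implausible(runs, features, bounds=bounds, age_limit_days=age_limit_days)
    clean = drop_flagged_days(runs, log)
    day_records = average_runs_per_day(clean)
    kept, removed = filter_min_days(day_records, min_days=min_days)
    # a dog whose every day was excluded has 0 surviving days and is
    # removed by the same rule, even though the day filter never saw it
    vanished = set(runs["dog_id"]) - set(day_records["dog_id"])
    removed = sorted(set(removed) | vanished)
    removed_rows = int(clean["dog_id"].isin(removed).sum())
    counts = {
        "rows_in": int(len(runs)),
        "rows_on_excluded_days": int(len(runs) - len(clean)),
        "rows_of_removed_dogs": removed_rows,
        "rows_out": int(len(clean) - removed_rows),
        "day_records": int(len(kept)),
        "dogs_removed": len(removed),
    }
    return PreprocessResult(
        day_records=kept, exclusions=log, removed_dogs=removed, counts=counts
    )
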