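"""Input/output for the three cohort tables and all result tables.

All files are plain CSV: comma-separated, UTF-8, ``.`` decimal separator,
header row required. Ages are integer days since birth — a single
unambiguous axis for the per-dog regressions (the clinical schedule mixes
weeks and months; the plausibility rules use days).

Tables
------
runs.csv      : dog_id, age_days, run_index, feature_id, value
                one gait-feature value for one dog on one day in one run
                (up to 3 consecutive walking trials per examination day)
dogs.csv      : dog_id, breed, diagnosis, pathological_side
features.csv  : feature_id, display_name, unit, exclusion_category,
                laterality, symmetry_pair
results.csv   : per-feature healthy-vs-HD comparison (see RESULTS_COLUMNS)
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import CatalogueError, IntegrityError, ParseError

RUNS_COLUMNS = ["dog_id", "age_days", "run_index", "feature_id", "value"]
DOGS_COLUMNS = ["dog_id", "breed", "diagnosis", "pathological_side"]
FEATURES_COLUMNS = [
    "feature_id",
    "display_name",
    "unit",
    "exclusion_category",
    "laterality",
    "symmetry_pair",
]
RESULTS_COLUMNS = [
    "feature_id",
    "n_healthy",
    "n_hd",
    "mean_healthy",
    "sd_healthy",
    "mean_hd",
    "sd_hd",
    "shapiro_p_healthy",
    "shapiro_p_hd",
    "t_stat",
    "p_value",
]

DIAGNOSES = ("healthy", "HD")
SIDES = ("left", "right", "none")
LATERALITIES = ("left", "right", "axial")
EXCLUSION_CATEGORIES = ("energy", "step_length", "withers", "none")


@dataclass(frozen=True)
class DogMeta:
    """Per-dog metadata: breed, radiographic diagnosis, pathological side.

    ``pathological_side`` is "left" or "right" for HD dogs and "none" for
    healthy dogs; the invariant is enforced at construction and at load.
    """

    dog_id: str
    breed: str
    diagnosis: str
    pathological_side: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise IntegrityError(
                f"dog {self.dog_id!r}: diagnosis must be one of {DIAGNOSES}, "
                f"got {self.diagnosis!r}"
            )
        if self.diagnosis == "HD" and self.pathological_side not in ("left", "right"):
            raise IntegrityError(
                f"dog {self.dog_id!r}: HD diagnosis requires pathological_side "
                f"'left' or 'right', got {self.pathological_side!r}"
            )
        if self.diagnosis == "healthy" and self.pathological_side != "none":
            raise IntegrityError(
                f"dog {self.dog_id!r}: healthy diagnosis requires "
                f"pathological_side 'none', got {self.pathological_side!r}"
            )


@dataclass(frozen=True)
class FeatureSpec:
    """One catalogue entry for a gait feature.

    ``exclusion_category`` selects which plausibility bounds apply to raw
    values of the feature; ``laterality`` says which body side the feature
    describes ("axial" for trunk/whole-body features); ``symmetry_pair`` is
    the mirrored counterpart used when aligning to the pathological side
    (empty for axial features).
    """

    feature_id: str
    display_name: str
    unit: str
    exclusion_category: str
    laterality: str
    symmetry_pair: str | None = None


def _read_csv(path, required_columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {required_columns}"
        )
    return df


def _numeric(
    df: pd.DataFrame, column: str, path, as_int: bool = False, allow_empty: bool = False
) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna()
    if allow_empty:
        bad &= df[column].astype(str).str.strip().ne("")
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: line {line}: cannot parse {column}={df[column][bad.idxmax()]!r}"
        )
    if as_int:
        if not np.allclose(out, np.round(out)):
            line = int((out != np.round(out)).idxmax()) + 2
            raise ParseError(f"{path}: line {line}: {column} must be an integer")
        out = out.astype(int)
    return out


def read_runs(path) -> pd.DataFrame:
    """Load a runs table and enforce its invariants.

    Returns a DataFrame with columns ``RUNS_COLUMNS``. Raises
    :class:`ParseError` naming the first malformed line, or
    :class:`IntegrityError` on duplicate (dog, day, run, feature) keys,
    non-positive ages, or run indices outside 1..3.
    """
    df = _read_csv(path, RUNS_COLUMNS)
    df = df[RUNS_COLUMNS].copy()
    df["age_days"] = _numeric(df, "age_days", path, as_int=True)
    df["run_index"] = _numeric(df, "run_index", path, as_int=True)
    df["value"] = _numeric(df, "value", path)
    return validate_runs(df, source=str(path))


def validate_runs(df: pd.DataFrame, source: str = "runs") -> pd.DataFrame:
    if (df["age_days"] <= 0).any():
        raise IntegrityError(f"{source}: age_days must be > 0")
    if (~df["run_index"].isin([1, 2, 3])).any():
        raise IntegrityError(f"{source}: run_index must be in {{1,2,3}}")
    key = ["dog_id", "age_days", "run_index", "feature_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise IntegrityError(
            f"{source}: duplicate (dog_id, age_days, run_index, feature_id) "
            f"key {tuple(first)}"
        )
    return df.reset_index(drop=True)


def read_dogs(path) -> pd.DataFrame:
    """Load the dog-metadata table; the diagnosis↔side invariant is enforced."""
    df = _read_csv(path, DOGS_COLUMNS)[DOGS_COLUMNS].copy()
    return validate_dogs(df, source=str(path))


def validate_dogs(df: pd.DataFrame, source: str = "dogs") -> pd.DataFrame:
    if df["dog_id"].duplicated().any():
        raise IntegrityError(f"{source}: duplicate dog_id")
    for row in df.itertuples(index=False):
        DogMeta(row.dog_id, row.breed, row.diagnosis, row.pathological_side)
    return df.reset_index(drop=True)


def read_features(path) -> pd.DataFrame:
    """Load a feature catalogue and check its internal consistency.

    The symmetry/laterality pairing must be symmetric: if a names b as its
    mirrored counterpart then b must name a.
    """
    df = _read_csv(path, FEATURES_COLUMNS)[FEATURES_COLUMNS].copy()
    return validate_features(df, source=str(path))


def validate_features(df: pd.DataFrame, source: str = "features") -> pd.DataFrame:
    if df["feature_id"].duplicated().any():
        raise CatalogueError(f"{source}: duplicate feature_id")
    bad_lat = ~df["laterality"].isin(LATERALITIES)
    if bad_lat.any():
        raise CatalogueError(
            f"{source}: laterality must be one of {LATERALITIES}, got "
            f"{df.loc[bad_lat.idxmax(), 'laterality']!r}"
        )
    bad_cat = ~df["exclusion_category"].isin(EXCLUSION_CATEGORIES)
    if bad_cat.any():
        raise CatalogueError(
            f"{source}: unknown exclusion_category "
            f"{df.loc[bad_cat.idxmax(), 'exclusion_category']!r}"
        )
    pair = dict(zip(df["feature_id"], df["symmetry_pair"].replace("", None)))
    for fid, mate in pair.items():
        if mate is None:
            continue
        if mate not in pair:
            raise CatalogueError(f"{source}: {fid}: symmetry_pair {mate!r} not in catalogue")
        if pair[mate] != fid:
            raise CatalogueError(
                f"{source}: symmetry_pair not symmetric: {fid} -> {mate} -> {pair[mate]}"
            )
    return df.reset_index(drop=True)


def load_default_features() -> pd.DataFrame:
    """The packaged default feature catalogue (editable copy: just save it)."""
    with resources.files("gaitvar.data").joinpath("default_features.csv").open("rb") as fh:
        return validate_features(
            pd.read_csv(fh, dtype=str, keep_default_na=False), source="default catalogue"
        )


def load_reference_group_stats() -> pd.DataFrame:
    """Published healthy-vs-HD reference summaries from the clinical cohort.

    Per feature: the reported p-value and the group means / standard
    deviations of the MSE instability score for 30 healthy and 14 HD dogs.
    ``pathological_limb_feature`` is 1 for the six features measured directly
    on the pathological limb. Used as the input for summary-statistic
    re-testing; the underlying raw measurements were never deposited.
    """
    with resources.files("gaitvar.data").joinpath("reference_group_stats.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    return df


def write_results(comparisons: pd.DataFrame, path) -> None:
    """Write a per-feature comparison table (columns ``RESULTS_COLUMNS``).

    Values round-trip bit-exactly through :func:`read_results`. An empty
    table is refused: a report with no rows is always a pipeline error.
    """
    if len(comparisons) == 0:
        raise IntegrityError("refusing to write an empty results table")
    missing = [c for c in RESULTS_COLUMNS if c not in comparisons.columns]
    if missing:
        raise IntegrityError(f"results table missing column(s) {missing}")
    comparisons[RESULTS_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    df = _read_csv(path, RESULTS_COLUMNS)[RESULTS_COLUMNS].copy()
    for col in RESULTS_COLUMNS[1:]:
        df[col] = _numeric(df, col, path, allow_empty=True)
    df["n_healthy"] = df["n_healthy"].astype(int)
    df["n_hd"] = df["n_hd"].astype(int)
    return df
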