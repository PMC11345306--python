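"""Per-dog linear detrending and the MSE gait-instability score.

Each dog's feature trajectory over the growth period is approximated by
ordinary least squares of value against age in days. Growth produces a
strong, breed- and dog-specific linear trend in most gait features; the
residuals res_k = y_k - (a + b * age_k) measure how unsteadily the dog
walked around its own trend, independent of breed and body size. The
instability score is the mean of the squared residuals,

    mse = (1/n) * sum_k res_k^2,

with n the number of measurement days. The divisor is n, not n - 2: the
score is defined as the plain mean of the squared deviations, and is used
only comparatively between groups. The degrees-of-freedom-corrected variant
(divisor n - 2, an unbiased estimate of the residual variance) is available
via ``ddof_correction=True``.

Lateralized features are expressed relative to the pathological limb before
grouping: for a dog whose pathological side differs from the reference
side, a left/right feature is swapped with its contralateral counterpart
and a diagonal symmetry feature with its mirrored pair; axial features are
unchanged. Healthy dogs have no pathological side and use a configurable
reference side (default "right").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CatalogueError, DegenerateSeriesError, SingularDesignError
from .preprocess import VisitSeries, iter_series

#: Minimum series length for a trend fit. A 2-point fit is exact, so its
#: mse is 0 by construction and would bias the score toward stability.
MIN_FIT_POINTS = 3

INSTABILITY_COLUMNS = [
    "dog_id",
    "diagnosis",
    "feature_id",
    "mse",
    "n_days",
    "slope",
    "intercept",
]


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of one dog's feature values against age, with residuals."""

    dog_id: str
    feature_id: str
    slope: float
    intercept: float
    residuals: np.ndarray
    mse: float
    n_days: int


def fit_linear_trend(series: VisitSeries, ddof_correction: bool = False) -> TrendFit:
    """Least-squares line through one visit series; residuals in age order.

    Raises :class:`DegenerateSeriesError` for series shorter than
    ``MIN_FIT_POINTS`` and :class:`SingularDesignError` when all ages
    coincide.
    """
    x = np.asarray(series.ages, dtype=float)
    y = np.asarray(series.values, dtype=float)
    n = len(x)
    if n < MIN_FIT_POINTS:
        raise DegenerateSeriesError(
            f"{series.dog_id}/{series.feature_id}: {n} point(s); "
            f"need at least {MIN_FIT_POINTS} for a trend fit"
        )
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise SingularDesignError(
            f"{series.dog_id}/{series.feature_id}: all ages identical"
        )
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    residuals = y - (intercept + slope * x)
    denom = n - 2 if ddof_correction else n
    mse = float(residuals @ residuals) / denom
    return TrendFit(
        dog_id=series.dog_id,
        feature_id=series.feature_id,
        slope=slope,
        intercept=intercept,
        residuals=residuals,
        mse=mse,
        n_days=n,
    )


def mse_score(fit: TrendFit) -> float:
    """Mean squared residual of a fit: squared, totalled, then averaged."""
    return float(fit.residuals @ fit.residuals) / fit.n_days


def align_to_pathological_side(
    feature_id: str,
    dog: pd.Series,
    features: pd.DataFrame,
    reference_side: str = "right",
) -> str:
    """Express a feature id relative to the dog's pathological side.

    ``dog`` needs fields ``diagnosis`` and ``pathological_side`` (a
    dogs-table row works). HD dogs use their pathological side; healthy dogs
    the ``reference_side``. If that side differs from ``reference_side``,
    lateralized and symmetry features map to their mirrored counterpart;
    axial features are always unchanged. Mirroring twice is the identity.
    """
    cat = features.set_index("feature_id") if features.index.name != "feature_id" else features
    if feature_id not in cat.index:
        raise CatalogueError(f"unknown feature id {feature_id!r}")
    laterality = cat.at[feature_id, "laterality"]
    if laterality == "axial":
        return feature_id
    side = dog["pathological_side"] if dog["diagnosis"] == "HD" else reference_side
    if side == reference_side:
        return feature_id
    mate = cat.at[feature_id, "symmetry_pair"]
    if not isinstance(mate, str) or mate == "":
        raise CatalogueError(
            f"lateralized feature {feature_id!r} has no mirrored counterpart "
            "in the catalogue"
        )
    return mate


def build_instability_table(
    day_records: pd.DataFrame,
    dogs: pd.DataFrame,
    features: pd.DataFrame,
    reference_side: str = "right",
    ddof_correction: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """One MSE row per dog x side-aligned feature with a fittable series.

    Series too short to fit (or with singular design) are skipped, never
    fatal; each skip is returned as a log entry
    ``{"dog_id", "feature_id", "reason"}``. Returns
    (table with ``INSTABILITY_COLUMNS``, skip log).
    """
    meta = dogs.set_index("dog_id")
    cat = features.set_index("feature_id")
    rows: list[dict] = []
    skipped: list[dict] = []
    for series in iter_series(day_records):
        if series.dog_id not in meta.index:
            skipped.append(
                {
                    "dog_id": series.dog_id,
                    "feature_id": series.feature_id,
                    "reason": "dog missing from metadata table",
                }
            )
            continue
        dog = meta.loc[series.dog_id]
        try:
            fit = fit_linear_trend(series, ddof_correction=ddof_correction)
        except DegenerateSeriesError as exc:
            skipped.append(
                {
                    "dog_id": series.dog_id,
                    "feature_id": series.feature_id,
                    "reason": str(exc),
                }
            )
            continue
        aligned = align_to_pathological_side(
            series.feature_id,
            dog,
            cat,
            reference_side=reference_side,
        )
        rows.append(
            {
                "dog_id": series.dog_id,
                "diagnosis": dog["diagnosis"],
                "feature_id": aligned,
                "mse": fit.mse,
                "n_days": fit.n_days,
                "slope": fit.slope,
                "intercept": fit.intercept,
            }
        )
    table = pd.DataFrame(rows, columns=INSTABILITY_COLUMNS)
    table = table.sort_values(["feature_id", "diagnosis", "dog_id"]).reset_index(drop=True)
    return table, skipped
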