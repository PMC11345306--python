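"""Healthy-vs-HD comparison of per-dog MSE instability scores.

Per feature: group means and SDs, a Shapiro-Wilk normality check in each
group, and a two-sided unpaired Student t-test (pooled variance,
df = n_a + n_b - 2) at alpha = 0.05. The pooled form is the default because
it reproduces the published p-values from the published group summaries;
Welch's unequal-variance test is available via ``equal_var=False``. A
failed normality check attaches a warning to the comparison but does not
switch the test to a nonparametric alternative, and no multiple-testing
correction is applied by default (``p_adjust`` offers Bonferroni/Holm for
users who want it).

``t_from_summary`` computes the identical pooled t-test from group summary
statistics alone, for verifying published tables when raw data are
unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CatalogueError, DegenerateSampleError, SampleSizeError
from .io import RESULTS_COLUMNS

BOXPLOT_COLUMNS = ["feature_id", "group", "min", "q1", "median", "q3", "max", "n_outliers"]


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float
    significant: bool


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value; refuses n < 3 or constant samples."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise SampleSizeError(f"Shapiro-Wilk needs n >= 3, got n={len(x)}")
    if np.all(x == x[0]):
        raise DegenerateSampleError("Shapiro-Wilk undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def two_sample_t(
    values_a, values_b, alpha: float = 0.05, equal_var: bool = True
) -> TTestResult:
    """Two-sided unpaired t-test on raw per-dog scores.

    Pooled-variance Student form by default; ``equal_var=False`` gives
    Welch's test. Each group needs at least two observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError(
            f"two-sample t-test needs n >= 2 per group, got {len(a)} and {len(b)}"
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


def t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Pooled two-sided Student t-test from group summary statistics.

    Algebraically identical to :func:`two_sample_t` applied to any raw data
    with these summaries. Returns ``(t_stat, p_value)``.
    """
    if n_a < 2 or n_b < 2:
        raise SampleSizeError(f"need n >= 2 per group, got {n_a} and {n_b}")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            raise DegenerateSampleError(
                "t statistic undefined: both SDs zero and means equal"
            )
        raise DegenerateSampleError("t statistic undefined: both SDs zero")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def significance_stars(p_value: float) -> str:
    """Conventional star annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_all_features(
    instability: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
    p_adjust: str | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-feature healthy-vs-HD comparison of MSE scores.

    ``instability`` needs columns dog_id, diagnosis, feature_id, mse.
    Returns ``(results, issues)``: one results row per feature with both
    groups present (columns ``RESULTS_COLUMNS`` plus ``significant`` and
    ``warning``), and an issue entry for every feature that had to be
    skipped (missing group, too few dogs) — nothing is silently dropped.
    ``p_adjust`` in {"bonferroni", "holm"} adds a ``p_adjusted`` column and
    bases ``significant`` on it.
    """
    rows: list[dict] = []
    issues: list[dict] = []
    for feature_id, grp in instability.groupby("feature_id", sort=True):
        healthy = grp.loc[grp["diagnosis"] == "healthy", "mse"].to_numpy()
        hd = grp.loc[grp["diagnosis"] == "HD", "mse"].to_numpy()
        if len(healthy) < 2 or len(hd) < 2:
            issues.append(
                {
                    "feature_id": feature_id,
                    "reason": (
                        f"needs >= 2 dogs per group, got healthy={len(healthy)}, "
                        f"HD={len(hd)}"
                    ),
                }
            )
            continue
        warning = ""
        shapiro_p = {}
        for name, vals in (("healthy", healthy), ("hd", hd)):
            try:
                shapiro_p[name] = shapiro_wilk(vals)
            except (SampleSizeError, DegenerateSampleError) as exc:
                shapiro_p[name] = np.nan
                warning += f"shapiro_{name}: {exc}; "
        try:
            tt = two_sample_t(healthy, hd, alpha=alpha, equal_var=equal_var)
        except (SampleSizeError, DegenerateSampleError) as exc:
            issues.append({"feature_id": feature_id, "reason": str(exc)})
            continue
        for name in ("healthy", "hd"):
            p = shapiro_p[name]
            if np.isfinite(p) and p < alpha:
                warning += f"non-normal {name} group (Shapiro-Wilk p={p:.3g}); "
        rows.append(
            {
                "feature_id": feature_id,
                "n_healthy": len(healthy),
                "n_hd": len(hd),
                "mean_healthy": float(healthy.mean()),
                "sd_healthy": float(healthy.std(ddof=1)),
                "mean_hd": float(hd.mean()),
                "sd_hd": float(hd.std(ddof=1)),
                "shapiro_p_healthy": shapiro_p["healthy"],
                "shapiro_p_hd": shapiro_p["hd"],
                "t_stat": tt.t_stat,
                "p_value": tt.p_value,
                "significant": tt.significant,
                "warning": warning.strip(),
            }
        )
    results = pd.DataFrame(rows, columns=RESULTS_COLUMNS + ["significant", "warning"])
    if p_adjust is not None and len(results) > 0:
        reject, p_adj, _, _ = multipletests(
            results["p_value"].to_numpy(), alpha=alpha, method=p_adjust
        )
        results["p_adjusted"] = p_adj
        results["significant"] = reject
    return results, issues


def _box_stats(values: np.ndarray) -> dict:
    # linear-interpolation quartiles, Tukey 1.5*IQR whiskers
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(len(values) - len(inside)),
    }


def export_boxplot_data(
    instability: pd.DataFrame,
    features: list[str] | None = None,
    fig_path=None,
    alpha: float = 0.05,
    equal_var: bool = True,
):
    """Box-whisker summaries (and optionally a figure) per feature and group.

    Returns a tidy DataFrame (columns ``BOXPLOT_COLUMNS``) with healthy and
    HD rows per feature. If ``fig_path`` is given, renders side-by-side
    boxes (healthy left, HD right) with significance stars from the pooled
    t-test. Features with an empty group are skipped with a warning;
    unknown feature ids raise :class:`CatalogueError`.
    """
    available = set(instability["feature_id"])
    if features is None:
        features = sorted(available)
    else:
        unknown = set(features) - available
        if unknown:
            raise CatalogueError(
                f"feature id(s) {sorted(unknown)} absent from the instability table"
            )
    if not features:
        raise CatalogueError("no features selected for the boxplot export")

    rows = []
    panels = []
    for feature_id in features:
        grp = instability[instability["feature_id"] == feature_id]
        healthy = grp.loc[grp["diagnosis"] == "healthy", "mse"].to_numpy()
        hd = grp.loc[grp["diagnosis"] == "HD", "mse"].to_numpy()
        if len(healthy) == 0 or len(hd) == 0:
            warnings.warn(
                f"{feature_id}: empty group (healthy n={len(healthy)}, "
                f"HD n={len(hd)}); skipped",
                stacklevel=2,
            )
            continue
        for group, vals in (("healthy", healthy), ("HD", hd)):
            rows.append({"feature_id": feature_id, "group": group, **_box_stats(vals)})
        try:
            stars = significance_stars(
                two_sample_t(healthy, hd, alpha=alpha, equal_var=equal_var).p_value
            )
        except (SampleSizeError, DegenerateSampleError):
            stars = "ns"
        panels.append((feature_id, healthy, hd, stars))

    tidy = pd.DataFrame(
        rows, columns=BOXPLOT_COLUMNS + ["whisker_low", "whisker_high"]
    )[BOXPLOT_COLUMNS]

    if fig_path is not None and panels:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ncol = min(3, len(panels))
        nrow = -(-len(panels) // ncol)
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False
        )
        for ax in axes.flat[len(panels):]:
            ax.set_visible(False)
        for ax, (feature_id, healthy, hd, stars) in zip(axes.flat, panels):
            ax.boxplot([healthy, hd], tick_labels=["healthy", "HD"], whis=1.5)
            ax.set_title(feature_id, fontsize=8)
            ax.set_ylabel("MSE")
            top = max(healthy.max(), hd.max())
            ax.annotate(stars, xy=(1.5, top), ha="center", fontsize=10)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)

    return tidy
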