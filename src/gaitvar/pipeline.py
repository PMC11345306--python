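"""End-to-end wiring: preprocess -> detrend -> group comparison.

Used by the command-line interface and by calibration checks; everything
here is a thin composition of the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import group_stats, instability, preprocess, synthetic
from .errors import GaitVarError


@dataclass
class AnalysisResult:
    preprocessing: preprocess.PreprocessResult
    instability: pd.DataFrame
    skipped_series: list
    results: pd.DataFrame
    comparison_issues: list


def analyze_cohort(
    runs: pd.DataFrame,
    dogs: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
    min_days: int = 4,
    reference_side: str = "right",
    bounds=None,
    equal_var: bool = True,
    ddof_correction: bool = False,
    p_adjust: str | None = None,
) -> AnalysisResult:
    """Run the full analysis on one cohort of raw run-level measurements."""
    pre = preprocess.run_preprocessing(runs, features, bounds=bounds, min_days=min_days)
    if len(pre.day_records) == 0:
        raise GaitVarError(
            "no dog passes the minimum-measurement-days filter; nothing to analyse"
        )
    table, skipped = instability.build_instability_table(
        pre.day_records,
        dogs,
        features,
        reference_side=reference_side,
        ddof_correction=ddof_correction,
    )
    results, issues = group_stats.compare_all_features(
        table, alpha=alpha, equal_var=equal_var, p_adjust=p_adjust
    )
    return AnalysisResult(
        preprocessing=pre,
        instability=table,
        skipped_series=skipped,
        results=results,
        comparison_issues=issues,
    )


def null_feature_config(seed: int = 0, implausible_rate: float = 0.02):
    """Small equal-dispersion cohort config for type-I-error calibration.

    One lateralized feature pair without plausibility bounds (extension)
    plus one bounded pair (step length) so the exclusion filter stays in
    the loop; group dispersions equalised. The per-feature type-I error of
    the pipeline does not depend on how many features are simulated.
    """
    return synthetic.CohortConfig(
        feature_ids=("extension_r", "extension_l", "step_length_r", "step_length_l"),
        implausible_rate=implausible_rate,
        seed=seed,
    ).null()


def null_pvalues(n_cohorts: int, seed: int = 0, alpha: float = 0.05) -> np.ndarray:
    """P-values of every per-feature test across simulated null cohorts.

    Each cohort is generated with equal group dispersion, pushed through
    the full pipeline (filters, day averaging, dog filter, detrending,
    side alignment, pooled t-tests); all per-feature p-values are pooled.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31)
    pvals: list[float] = []
    for s in seeds:
        cohort = synthetic.simulate(null_feature_config(seed=int(s)))
        res = analyze_cohort(cohort.runs, cohort.dogs, cohort.features, alpha=alpha)
        pvals.extend(res.results["p_value"].tolist())
    return np.asarray(pvals)


def null_rejection_rate(n_cohorts: int, seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of null-pipeline tests rejecting at ``alpha``."""
    p = null_pvalues(n_cohorts, seed=seed, alpha=alpha)
    return float((p < alpha).mean())
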