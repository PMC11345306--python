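"""Synthetic longitudinal gait cohorts with the study's structure.

The simulator emulates a growing-dog cohort followed from 12 weeks to 15
months of age: monthly examinations from day 84 to day 196, then every two
months up to day 450 (deterministic schedule 84, 112, 140, 168, 196, 256,
316, 376, 436), with 1-3 consecutive walking trials per examination day.
Each gait feature follows a linear growth trend with additive Gaussian
noise between visits and a smaller within-day run noise:

    value(dog, feature, day, run)
        = a_f + breed_offset + b_f * day + eps_visit + eps_run,
    eps_visit ~ N(0, sigma_group^2),  eps_run ~ N(0, run_sd^2).

Dogs diagnosed with hip dysplasia carry an inflated between-visit noise
(sigma_hd > sigma_healthy) on the features of their pathological limb —
assigned left/right with equal probability — and on group-sensitive axial
features; everything else uses the healthy dispersion. Downstream, the
per-dog linear detrending turns this dispersion difference into higher MSE
instability scores for the HD group, which is the effect the pipeline is
built to detect.

Default per-feature noise levels are calibrated so that the pipeline's MSE
group means land near the published reference values for the unbounded
features (sigma = sqrt(mse_target * n/(n-2)) at n = 9 scheduled visits).
The step-length and withers defaults are instead chosen physically small:
dispersion at the published step-length MSE scale would constantly push
raw values across the (0.1, 0.6] m plausibility bounds, and the simulator
guarantees that clean days are essentially never excluded. These constants
are stand-ins for the study conditions, not estimates of them.

Optionally, examination days receive injected implausible values (e.g. a
2 m step length) at a configurable rate, with every injection recorded in a
truth table so the preprocessing filters can be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import FEATURES_COLUMNS, load_default_features, validate_dogs, validate_runs

TRUTH_COLUMNS = ["dog_id", "age_days", "run_index", "feature_id", "value", "category"]

#: Injected out-of-bounds values per exclusion category (step length of 2 m
#: mimics the doubly-detected step frequency artefact).
INJECTION_VALUES = {"step_length": 2.0, "withers": 0.7, "energy": 250.0}


@dataclass(frozen=True)
class FeatureParams:
    """Growth-trend and noise parameters of one simulated feature.

    ``intercept`` (value units at day 0) and ``slope`` (units/day) define
    the linear growth trend; ``sigma_healthy``/``sigma_hd`` the
    between-visit noise SD per group; ``run_sd`` the within-day trial noise
    SD. ``group_sensitive=False`` makes the feature ignore diagnosis
    (used for body measurements like withers height).
    """

    intercept: float
    slope: float
    sigma_healthy: float
    sigma_hd: float
    run_sd: float
    group_sensitive: bool = True

    def __post_init__(self) -> None:
        if not self.sigma_healthy > 0:
            raise ValueError("sigma_healthy must be > 0")
        if self.sigma_hd < self.sigma_healthy:
            raise ValueError("sigma_hd must be >= sigma_healthy")
        if self.run_sd < 0:
            raise ValueError("run_sd must be >= 0")


def _params(mse_healthy, mse_hd, intercept, slope, n_visits=9, **kw) -> FeatureParams:
    f = n_visits / (n_visits - 2)
    return FeatureParams(
        intercept=intercept,
        slope=slope,
        sigma_healthy=float(np.sqrt(mse_healthy * f)),
        sigma_hd=float(np.sqrt(mse_hd * f)),
        run_sd=float(0.1 * np.sqrt(mse_healthy * f)),
        **kw,
    )


def default_feature_params() -> dict[str, FeatureParams]:
    """Per-feature defaults; left/right counterparts share parameters."""
    base = {
        "extension": _params(2.03, 2.91, intercept=20.0, slope=0.010),
        "step_length": FeatureParams(0.163, 6.8e-4, 0.020, 0.028, 0.005),
        "max_acc_amp": _params(2.16, 3.41, intercept=8.0, slope=0.010),
        "ventral_acceleration": _params(144.39, 230.61, intercept=68.0, slope=0.143),
        "max_gyr_amp": _params(0.57, 0.83, intercept=3.0, slope=0.004),
        "std_acc": _params(0.43, 0.61, intercept=2.0, slope=0.003),
        "sym_ext": _params(12.06, 16.86, intercept=100.0, slope=0.0),
        "sym_maxacc_ff": _params(3.95, 5.19, intercept=100.0, slope=0.0),
        "sym_maxacc_fr_hl": _params(10.40, 14.34, intercept=100.0, slope=0.0),
        "sym_maxacc_fl_hr": _params(9.58, 13.02, intercept=100.0, slope=0.0),
        "sym_normstep": _params(3.26, 8.60, intercept=100.0, slope=0.0),
        "sym_step": _params(3.26, 8.60, intercept=100.0, slope=0.0),
        "sym_pr_lumbar": _params(2.21, 2.98, intercept=100.0, slope=0.0),
        "withers_height": FeatureParams(
            0.19, 8.0e-4, 0.008, 0.008, 0.003, group_sensitive=False
        ),
    }
    by_id = {
        "extension_r": "extension",
        "extension_l": "extension",
        "step_length_r": "step_length",
        "step_length_l": "step_length",
        "max_acc_amp_r": "max_acc_amp",
        "max_acc_amp_l": "max_acc_amp",
        "ventral_acceleration_r": "ventral_acceleration",
        "ventral_acceleration_l": "ventral_acceleration",
        "max_gyr_amp_r": "max_gyr_amp",
        "max_gyr_amp_l": "max_gyr_amp",
        "std_acc_r": "std_acc",
        "std_acc_l": "std_acc",
        "sym_ext_fl_hr": "sym_ext",
        "sym_ext_fr_hl": "sym_ext",
        "sym_maxacc_fr_fl": "sym_maxacc_ff",
        "sym_maxacc_fl_fr": "sym_maxacc_ff",
        "sym_maxacc_fr_hl": "sym_maxacc_fr_hl",
        "sym_maxacc_fl_hr": "sym_maxacc_fl_hr",
        "sym_normstep_fr_hl": "sym_normstep",
        "sym_normstep_fl_hr": "sym_normstep",
        "sym_step_fr_hl": "sym_step",
        "sym_step_fl_hr": "sym_step",
        "sym_pr_lumbar": "sym_pr_lumbar",
        "withers_height": "withers_height",
    }
    return {fid: base[key] for fid, key in by_id.items()}


DEFAULT_BREED_MIX = (
    ("Australian Shepherd", 37),
    ("Golden Retriever", 11),
    ("Rottweiler", 6),
)

#: Additive breed offset as a fraction of the feature intercept. Irrelevant
#: to the MSE score (per-dog detrending absorbs any per-dog constant) but
#: keeps raw tables breed-structured.
DEFAULT_BREED_OFFSET_FRAC = {
    "Australian Shepherd": 0.0,
    "Golden Retriever": 0.02,
    "Rottweiler": 0.05,
}


@dataclass(frozen=True)
class CohortConfig:
    """Simulator configuration; the defaults are the study conditions.

    44 dogs, 14 with HD; breed mix 37:11:6; first visit at day 84, monthly
    to day 196, then bimonthly up to day 450; 1-3 runs per day.
    """

    n_dogs: int = 44
    n_hd: int = 14
    breed_mix: tuple = DEFAULT_BREED_MIX
    first_visit_day: int = 84
    monthly_interval: int = 28
    monthly_until_day: int = 196
    bimonthly_interval: int = 60
    last_day: int = 450
    run_count_probs: tuple = (0.2, 0.3, 0.5)
    implausible_rate: float = 0.0
    feature_ids: tuple | None = None
    feature_params: dict = field(default_factory=default_feature_params)
    breed_offset_frac: dict = field(default_factory=lambda: dict(DEFAULT_BREED_OFFSET_FRAC))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")
        if not 0 <= self.n_hd <= self.n_dogs:
            raise ValueError("n_hd must satisfy 0 <= n_hd <= n_dogs")
        if abs(sum(self.run_count_probs) - 1.0) > 1e-9 or len(self.run_count_probs) != 3:
            raise ValueError("run_count_probs must be 3 probabilities summing to 1")
        if not 0.0 <= self.implausible_rate <= 1.0:
            raise ValueError("implausible_rate must be in [0, 1]")
        if not self.schedule():
            raise ValueError("empty visit schedule")
        if max(self.schedule()) > 450:
            raise ValueError("schedule extends past the 450-day age bound")

    def schedule(self) -> list[int]:
        """Deterministic examination days: monthly, then bimonthly."""
        days = []
        d = self.first_visit_day
        while d <= self.monthly_until_day:
            days.append(d)
            d += self.monthly_interval
        d = days[-1] + self.bimonthly_interval if days else self.first_visit_day
        while d <= self.last_day:
            days.append(d)
            d += self.bimonthly_interval
        return days

    def catalogue(self) -> pd.DataFrame:
        """Feature catalogue used for generation (closed under mirroring)."""
        cat = load_default_features()
        if self.feature_ids is None:
            return cat
        wanted = set(self.feature_ids)
        pair = dict(zip(cat["feature_id"], cat["symmetry_pair"]))
        for fid in list(wanted):
            if fid not in pair:
                raise ValueError(f"unknown feature id {fid!r}")
            if pair[fid]:
                wanted.add(pair[fid])
        return cat[cat["feature_id"].isin(wanted)].reset_index(drop=True)

    def null(self) -> "CohortConfig":
        """Copy with equal dispersion in both groups (no HD effect)."""
        params = {
            fid: replace(p, sigma_hd=p.sigma_healthy)
            for fid, p in self.feature_params.items()
        }
        return replace(self, feature_params=params)


def _breed_counts(mix, n_dogs: int) -> list[int]:
    # largest-remainder apportionment of the breed proportions
    weights = np.array([w for _, w in mix], dtype=float)
    quota = weights / weights.sum() * n_dogs
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n_dogs - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _make_dogs(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = max(2, len(str(config.n_dogs)))
    ids = [f"d{i + 1:0{width}d}" for i in range(config.n_dogs)]
    breeds = []
    for (breed, _), count in zip(config.breed_mix, _breed_counts(config.breed_mix, config.n_dogs)):
        breeds.extend([breed] * count)
    hd_idx = set(rng.choice(config.n_dogs, size=config.n_hd, replace=False).tolist())
    sides = rng.choice(["left", "right"], size=config.n_dogs)
    rows = [
        {
            "dog_id": ids[i],
            "breed": breeds[i],
            "diagnosis": "HD" if i in hd_idx else "healthy",
            "pathological_side": sides[i] if i in hd_idx else "none",
        }
        for i in range(config.n_dogs)
    ]
    return validate_dogs(pd.DataFrame(rows), source="simulated dogs")


def _dog_sigma(params: FeatureParams, laterality: str, dog) -> float:
    if dog.diagnosis != "HD" or not params.group_sensitive:
        return params.sigma_healthy
    if laterality == "axial" or laterality == dog.pathological_side:
        return params.sigma_hd
    return params.sigma_healthy


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a clean cohort: (runs, dogs, feature catalogue).

    A fixed seed yields byte-identical tables. Use
    :func:`inject_implausibles` (or :func:`simulate`) to add the
    out-of-bounds artefacts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    dogs = _make_dogs(config, rng)
    catalogue = config.catalogue()
    days = np.array(config.schedule())
    n_dogs, n_days = config.n_dogs, len(days)

    k = rng.choice([1, 2, 3], p=config.run_count_probs, size=(n_dogs, n_days))
    rep = k.ravel()
    total = int(rep.sum())
    dog_of_run = np.repeat(np.repeat(np.arange(n_dogs), n_days), rep)
    day_of_run = np.repeat(np.tile(np.arange(n_days), n_dogs), rep)
    starts = np.concatenate([[0], np.cumsum(rep)[:-1]])
    run_index = np.arange(total) - np.repeat(starts, rep) + 1

    frames = []
    for feat in catalogue.itertuples(index=False):
        params: FeatureParams = config.feature_params[feat.feature_id]
        sigma = np.array([_dog_sigma(params, feat.laterality, d) for d in dogs.itertuples()])
        offset = np.array(
            [params.intercept * config.breed_offset_frac.get(b, 0.0) for b in dogs["breed"]]
        )
        day_value = (
            params.intercept
            + offset[:, None]
            + params.slope * days[None, :]
            + rng.normal(size=(n_dogs, n_days)) * sigma[:, None]
        )
        value = day_value[dog_of_run, day_of_run]
        if params.run_sd > 0:
            value = value + rng.normal(0.0, params.run_sd, size=total)
        frames.append(
            pd.DataFrame(
                {
                    "dog_id": dogs["dog_id"].to_numpy()[dog_of_run],
                    "age_days": days[day_of_run],
                    "run_index": run_index,
                    "feature_id": feat.feature_id,
                    "value": value,
                }
            )
        )
    runs = pd.concat(frames, ignore_index=True)
    runs = runs.sort_values(
        ["dog_id", "age_days", "run_index", "feature_id"], kind="mergesort"
    ).reset_index(drop=True)
    return validate_runs(runs, source="simulated runs"), dogs, catalogue


def inject_implausibles(
    runs: pd.DataFrame,
    config: CohortConfig,
    catalogue: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overwrite one run value on randomly selected dog-days with an
    out-of-bounds artefact.

    Each dog-day is hit independently with probability
    ``config.implausible_rate``; the injected value violates the exclusion
    bound of a bounded-category feature measured that day (days with no
    bounded feature cannot be hit). Returns ``(runs', truth)`` where
    ``truth`` (columns ``TRUTH_COLUMNS``) records every injection for
    exact filter testing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    catalogue = config.catalogue() if catalogue is None else catalogue
    category = dict(zip(catalogue["feature_id"], catalogue["exclusion_category"]))
    out = runs.copy()
    truth_rows: list[dict] = []
    if config.implausible_rate > 0:
        bounded = {f for f, c in category.items() if c != "none"}
        days = out[["dog_id", "age_days"]].drop_duplicates().sort_values(
            ["dog_id", "age_days"]
        )
        hit = rng.random(len(days)) < config.implausible_rate
        for (dog_id, age_days), selected in zip(
            days.itertuples(index=False), hit
        ):
            if not selected:
                continue
            day_mask = (out["dog_id"] == dog_id) & (out["age_days"] == age_days)
            candidates = sorted(set(out.loc[day_mask, "feature_id"]) & bounded)
            if not candidates:
                continue
            fid = candidates[int(rng.integers(len(candidates)))]
            cat = category[fid]
            bad_value = INJECTION_VALUES[cat]
            row_mask = day_mask & (out["feature_id"] == fid)
            target = out.index[row_mask][0]  # first run of the day
            out.loc[target, "value"] = bad_value
            truth_rows.append(
                {
                    "dog_id": dog_id,
                    "age_days": age_days,
                    "run_index": int(out.loc[target, "run_index"]),
                    "feature_id": fid,
                    "value": bad_value,
                    "category": cat,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return out, truth


@dataclass
class SimulatedCohort:
    runs: pd.DataFrame
    dogs: pd.DataFrame
    features: pd.DataFrame
    truth: pd.DataFrame


def simulate(config: CohortConfig) -> SimulatedCohort:
    """Clean cohort plus injected implausibles, in one call."""
    runs, dogs, catalogue = simulate_cohort(config)
    runs, truth = inject_implausibles(runs, config, catalogue)
    return SimulatedCohort(runs=runs, dogs=dogs, features=catalogue, truth=truth)


def expected_mse(
    sigma: float, n_days: int, run_sd: float = 0.0, e_inv_runs: float = 1.0
) -> float:
    """Expected MSE score of an OLS fit to a noisy line.

    With i.i.d. noise of variance s^2 around a true line and an OLS fit
    consuming 2 degrees of freedom, E[sum res_k^2] = (n - 2) s^2, so the
    divisor-n score has expectation s^2 (n - 2)/n. Day-averaged run noise
    contributes run_sd^2 * E[1/k] to s^2.
    """
    s2 = sigma**2 + run_sd**2 * e_inv_runs
    return s2 * (n_days - 2) / n_days


@dataclass
class TruthReport:
    """Analytic expectations implied by a config, for use as test oracles."""

    n_scheduled_days: int
    e_inv_runs: float
    expected_mse: pd.DataFrame  # feature_id, expected_mse_healthy, expected_mse_hd
    p_day_excluded: float
    p_dog_removed: float


def truth_report(config: CohortConfig, min_days: int = 4) -> TruthReport:
    """Expected per-group MSE per feature and expected filter casualties.

    The MSE expectations use the full scheduled visit count; with a
    non-zero injection rate they are exact only conditionally on a dog
    keeping all scheduled days (day losses shift the (n-2)/n factor
    slightly). ``p_dog_removed`` treats day exclusions as independent
    Bernoulli events, which matches the injection mechanism exactly when
    every day carries a bounded-category feature.
    """
    n = len(config.schedule())
    probs = np.asarray(config.run_count_probs)
    e_inv = float((probs / np.array([1.0, 2.0, 3.0])).sum())
    catalogue = config.catalogue()
    has_bounded = bool((catalogue["exclusion_category"] != "none").any())
    rate = config.implausible_rate if has_bounded else 0.0
    rows = []
    for fid in catalogue["feature_id"]:
        p = config.feature_params[fid]
        rows.append(
            {
                "feature_id": fid,
                "expected_mse_healthy": expected_mse(p.sigma_healthy, n, p.run_sd, e_inv),
                "expected_mse_hd": expected_mse(p.sigma_hd, n, p.run_sd, e_inv),
            }
        )
    from scipy.stats import binom

    p_removed = float(binom.cdf(min_days - 1, n, 1.0 - rate))
    return TruthReport(
        n_scheduled_days=n,
        e_inv_runs=e_inv,
        expected_mse=pd.DataFrame(rows),
        p_day_excluded=rate,
        p_dog_removed=p_removed,
    )


def predict_removed_dogs(
    truth: pd.DataFrame, dogs: pd.DataFrame, n_scheduled_days: int, min_days: int = 4
) -> set[str]:
    """Dogs the min-days filter must remove, derived from the truth table."""
    flagged = truth.groupby("dog_id")["age_days"].nunique() if len(truth) else pd.Series(dtype=int)
    out = set()
    for dog_id in dogs["dog_id"]:
        if n_scheduled_days - int(flagged.get(dog_id, 0)) < min_days:
            out.add(dog_id)
    return out
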