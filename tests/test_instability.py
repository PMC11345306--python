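import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitvar import instability, pipeline, synthetic
from gaitvar.errors import CatalogueError, DegenerateSeriesError, SingularDesignError
from gaitvar.preprocess import VisitSeries


def series(ages, values, dog="d1", feature="extension_r"):
    return VisitSeries(dog, feature, np.asarray(ages, float), np.asarray(values, float))


def normal_equations_fit(x, y):
    """Independent oracle: solve X'X beta = X'y explicitly."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]  # slope, intercept


class TestFitLinearTrend:
    def test_collinear_points_fit_exactly(self):
        # closed form: 3 points on the line y = 4 + x/14
        fit = instability.fit_linear_trend(series([84, 112, 140], [10, 12, 14]))
        assert fit.slope == pytest.approx(1 / 14, rel=1e-12)
        assert fit.intercept == pytest.approx(4.0, rel=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        assert fit.mse == pytest.approx(0.0, abs=1e-24)

    def test_constant_values_give_zero_slope(self):
        fit = instability.fit_linear_trend(series([84, 112, 140, 168], [7, 7, 7, 7]))
        assert fit.slope == 0.0
        assert fit.intercept == 7.0

    def test_hand_calculated_normal_equations_case(self):
        # x=(0,1,2), y=(0,1,0): x mean 1, y mean 1/3, Sxy=0 -> slope 0,
        # intercept 1/3, residuals (-1/3, 2/3, -1/3), mse = (1/3)(6/9) = 2/9
        fit = instability.fit_linear_trend(series([0, 1, 2], [0, 1, 0]))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.intercept == pytest.approx(1 / 3, rel=1e-12)
        np.testing.assert_allclose(fit.residuals, [-1 / 3, 2 / 3, -1 / 3], atol=1e-12)
        assert instability.mse_score(fit) == pytest.approx(2 / 9, rel=1e-12)
        assert fit.mse == pytest.approx(2 / 9, rel=1e-12)

    def test_residuals_sum_to_zero_and_match_oracles(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 12))
            x = np.sort(rng.choice(np.arange(50, 500), size=n, replace=False)).astype(float)
            y = rng.normal(size=n) * rng.uniform(0.1, 50)
            fit = instability.fit_linear_trend(series(x, y))
            slope_o, intercept_o = normal_equations_fit(x, y)
            assert fit.slope == pytest.approx(slope_o, rel=1e-10, abs=1e-12)
            assert fit.intercept == pytest.approx(intercept_o, rel=1e-10, abs=1e-12)
            lr = stats.linregress(x, y)
            assert fit.slope == pytest.approx(lr.slope, rel=1e-10, abs=1e-12)
            assert abs(fit.residuals.sum()) < 1e-8

    def test_mse_invariant_under_affine_shift_of_age(self, rng):
        x = np.array([84.0, 112.0, 140.0, 196.0, 256.0, 316.0])
        y = rng.normal(size=len(x))
        base = instability.fit_linear_trend(series(x, y)).mse
        shifted = instability.fit_linear_trend(series(x, y + 0.37 * x - 12.0)).mse
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_ddof_correction_rescales_mse(self):
        fit_n = instability.fit_linear_trend(series([0, 1, 2], [0, 1, 0]))
        fit_c = instability.fit_linear_trend(
            series([0, 1, 2], [0, 1, 0]), ddof_correction=True
        )
        assert fit_c.mse == pytest.approx(fit_n.mse * 3 / 1, rel=1e-12)

    def test_short_series_refused(self):
        with pytest.raises(DegenerateSeriesError):
            instability.fit_linear_trend(series([84, 112], [1, 2]))

    def test_identical_ages_refused(self):
        # VisitSeries itself refuses non-increasing ages, so the singular
        # design must be provoked on a hand-built object.
        s = VisitSeries.__new__(VisitSeries)
        object.__setattr__(s, "dog_id", "d1")
        object.__setattr__(s, "feature_id", "f")
        object.__setattr__(s, "ages", np.array([84.0, 84.0, 84.0]))
        object.__setattr__(s, "values", np.array([1.0, 2.0, 3.0]))
        with pytest.raises(SingularDesignError):
            instability.fit_linear_trend(s)

    def test_expected_mse_under_gaussian_noise(self, rng):
        # E[mse] = sigma^2 (n-2)/n for OLS with intercept: n=10 -> 0.8
        n, reps = 10, 10_000
        x = np.linspace(84, 436, n)
        mses = np.empty(reps)
        for i in range(reps):
            y = 1.0 + 0.01 * x + rng.normal(size=n)
            mses[i] = instability.fit_linear_trend(series(x, y)).mse
        assert mses.mean() == pytest.approx(0.8, abs=0.02)


class TestAlignment:
    @pytest.fixture()
    def dogs(self):
        return pd.DataFrame(
            [
                ("h1", "Australian Shepherd", "healthy", "none"),
                ("left1", "Australian Shepherd", "HD", "left"),
                ("right1", "Rottweiler", "HD", "right"),
            ],
            columns=["dog_id", "breed", "diagnosis", "pathological_side"],
        ).set_index("dog_id", drop=False)

    def test_symmetry_feature_mirrors_for_left_pathological_dog(self, features, dogs):
        out = instability.align_to_pathological_side(
            "sym_maxacc_fr_hl", dogs.loc["left1"], features
        )
        assert out == "sym_maxacc_fl_hr"

    def test_lateralized_feature_swaps_side(self, features, dogs):
        out = instability.align_to_pathological_side("extension_l", dogs.loc["left1"], features)
        assert out == "extension_r"

    def test_axial_feature_never_changes(self, features, dogs):
        for dog in ("h1", "left1", "right1"):
            assert (
                instability.align_to_pathological_side("sym_pr_lumbar", dogs.loc[dog], features)
                == "sym_pr_lumbar"
            )

    def test_reference_side_match_is_identity(self, features, dogs):
        assert (
            instability.align_to_pathological_side("extension_r", dogs.loc["right1"], features)
            == "extension_r"
        )
        assert (
            instability.align_to_pathological_side("extension_r", dogs.loc["h1"], features)
            == "extension_r"
        )

    def test_mirroring_is_an_involution(self, features, dogs):
        for fid in features["feature_id"]:
            once = instability.align_to_pathological_side(fid, dogs.loc["left1"], features)
            twice = instability.align_to_pathological_side(once, dogs.loc["left1"], features)
            assert twice == fid

    def test_reference_side_selects_which_dogs_mirror(self, features, dogs):
        # healthy dogs adopt the reference side, so they never mirror;
        # with reference "left" it is the right-pathological dogs that do
        out_h = instability.align_to_pathological_side(
            "extension_r", dogs.loc["h1"], features, reference_side="left"
        )
        assert out_h == "extension_r"
        out_r = instability.align_to_pathological_side(
            "extension_r", dogs.loc["right1"], features, reference_side="left"
        )
        assert out_r == "extension_l"

    def test_unknown_feature_raises(self, features, dogs):
        with pytest.raises(CatalogueError):
            instability.align_to_pathological_side("nope", dogs.loc["h1"], features)


class TestInstabilityTable:
    def test_cardinality_two_dogs_three_features(self, features):
        rows = []
        for dog in ("a", "b"):
            for fid in ("extension_r", "extension_l", "sym_pr_lumbar"):
                for day in (84, 112, 140, 168):
                    rows.append({"dog_id": dog, "age_days": day, "feature_id": fid, "value": day * 0.01})
        dogs = pd.DataFrame(
            [("a", "x", "healthy", "none"), ("b", "x", "HD", "right")],
            columns=["dog_id", "breed", "diagnosis", "pathological_side"],
        )
        table, skipped = instability.build_instability_table(pd.DataFrame(rows), dogs, features)
        assert len(table) == 6
        assert skipped == []
        assert set(table["diagnosis"]) == {"healthy", "HD"}

    def test_two_point_series_skipped_with_log_entry(self, features):
        rows = [
            {"dog_id": "a", "age_days": d, "feature_id": "extension_r", "value": 1.0}
            for d in (84, 112, 140, 168)
        ] + [
            {"dog_id": "a", "age_days": d, "feature_id": "extension_l", "value": 1.0}
            for d in (84, 112)
        ]
        dogs = pd.DataFrame(
            [("a", "x", "healthy", "none")],
            columns=["dog_id", "breed", "diagnosis", "pathological_side"],
        )
        table, skipped = instability.build_instability_table(pd.DataFrame(rows), dogs, features)
        assert list(table["feature_id"]) == ["extension_r"]
        assert len(skipped) == 1 and skipped[0]["feature_id"] == "extension_l"

    def test_noise_free_cohort_has_zero_mse_everywhere(self):
        config = synthetic.CohortConfig(seed=4, feature_ids=("extension_r",))
        params = {
            fid: synthetic.FeatureParams(p.intercept, p.slope, 1e-12, 1e-12, 0.0)
            for fid, p in config.feature_params.items()
        }
        cohort = synthetic.simulate(
            synthetic.CohortConfig(seed=4, feature_ids=("extension_r",), feature_params=params)
        )
        res = pipeline.analyze_cohort(cohort.runs, cohort.dogs, cohort.features)
        assert (res.instability["mse"] < 1e-18).all()
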