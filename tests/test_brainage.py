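"""Brain-age model, gap computation, bias correction and correlate tests."""

import numpy as np
import pandas as pd
import pytest

from neuronorm import atlas, brainage, synthetic
from neuronorm.brainage import (
    BrainAgeModel,
    compute_gap,
    fit_brainage,
    group_t_test,
    moderation_regression,
    pearson_corr_test,
    pearson_p_from_r,
)

from conftest import MINI_FEATURES

MINI_MODEL_FEATURES = MINI_FEATURES + list(atlas.COVARIATES)


@pytest.fixture(scope="module")
def mini_model(mini_reference):
    return fit_brainage(mini_reference, "F", feature_names=MINI_MODEL_FEATURES, seed=0)


def _trivial_model(intercept, bias=None):
    return BrainAgeModel(
        sex="F",
        feature_names=("x",),
        center=np.zeros(1),
        scale=np.ones(1),
        coef=np.zeros(1),
        intercept=intercept,
        alpha=1.0,
        age_range=(3.0, 90.0),
        bias_poly=None if bias is None else np.asarray(bias, dtype=float),
    )


class TestFit:
    def test_age_signal_recovered(self, mini_model, mini_trajectories):
        spec = synthetic.CohortSpec(
            n_subjects=400, age_range=(3.0, 90.0), sex_ratio=1.0,
            group="reference", seed=55,
        )
        heldout = synthetic.make_reference_cohort(
            spec, mini_trajectories, features=MINI_FEATURES
        )
        pred = mini_model.predict_age(heldout)
        mae = np.abs(pred - heldout["age"]).mean()
        assert mae < 0.5 * heldout["age"].std()

    def test_refit_deterministic(self, mini_reference):
        m1 = fit_brainage(mini_reference, "M", feature_names=MINI_MODEL_FEATURES, seed=4)
        m2 = fit_brainage(mini_reference, "M", feature_names=MINI_MODEL_FEATURES, seed=4)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.intercept == m2.intercept and m1.alpha == m2.alpha

    def test_too_small_reference_rejected(self, mini_reference):
        with pytest.raises(ValueError, match="too few"):
            fit_brainage(
                mini_reference.head(30), "F", feature_names=MINI_MODEL_FEATURES
            )

    def test_age_independent_features_motivate_bias_correction(self):
        """With no age signal, raw gaps regress to the mean (strong negative
        age correlation); the correction removes the trend."""
        rng = np.random.default_rng(8)
        n = 600

        def make(n):
            return pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(n)],
                    "age": rng.uniform(20, 70, n),
                    "sex": "F",
                    **{f"f{j}": rng.normal(size=n) for j in range(8)},
                }
            )

        feats = [f"f{j}" for j in range(8)]
        m = fit_brainage(make(n), "F", feature_names=feats, bias_correction=True, seed=0)
        gaps = compute_gap(m, make(n))  # held-out draw from the same process
        raw_corr = np.corrcoef(gaps["gap_raw"], gaps["age"])[0, 1]
        assert raw_corr < -0.9
        # correction removes the systematic trend: residual slope in
        # years-per-year is near zero (the raw slope is near -1)
        slope = np.polyfit(gaps["age"], gaps["gap"], 1)[0]
        assert abs(slope) < 0.02

    def test_serialization_round_trip(self, mini_model, mini_reference, tmp_path):
        path = tmp_path / "bam.json"
        mini_model.save(path)
        loaded = BrainAgeModel.load(path)
        sub = mini_reference.loc[mini_reference.sex == "F"].head(50)
        np.testing.assert_array_equal(
            mini_model.predict_age(sub), loaded.predict_age(sub)
        )


class TestGap:
    def test_gap_arithmetic(self):
        m = _trivial_model(intercept=25.0)
        df = pd.DataFrame(
            {"subject_id": ["s1"], "age": [22.3], "sex": ["F"], "x": [0.0]}
        )
        g = compute_gap(m, df)
        assert g["gap"].iloc[0] == pytest.approx(2.7)

    def test_bias_correction_applied(self):
        m = _trivial_model(intercept=25.0, bias=(0.5, 1.0))  # gap trend 0.5*age + 1
        df = pd.DataFrame(
            {"subject_id": ["s1"], "age": [20.0], "sex": ["F"], "x": [0.0]}
        )
        g = compute_gap(m, df)
        assert g["gap_raw"].iloc[0] == pytest.approx(5.0)
        assert g["gap"].iloc[0] == pytest.approx(5.0 - (1.0 + 0.5 * 20.0))

    def test_sex_mismatch_rejected(self):
        m = _trivial_model(intercept=25.0)
        df = pd.DataFrame(
            {"subject_id": ["s1"], "age": [22.0], "sex": ["M"], "x": [0.0]}
        )
        with pytest.raises(ValueError, match="sex"):
            compute_gap(m, df)

    def test_heldout_reference_gap_near_zero(self, mini_model, mini_trajectories):
        spec = synthetic.CohortSpec(
            n_subjects=600, age_range=(3.0, 90.0), sex_ratio=1.0,
            group="reference", seed=60,
        )
        heldout = synthetic.make_reference_cohort(
            spec, mini_trajectories, features=MINI_FEATURES
        )
        gaps = compute_gap(mini_model, heldout)
        assert abs(gaps["gap"].mean()) < 0.5
        assert abs(np.corrcoef(gaps["gap"], gaps["age"])[0, 1]) < 0.1


class TestCorrelates:
    def test_perfect_linear_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_corr_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_constructed_orthogonality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        r, p = pearson_corr_test(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_p_from_r(self):
        # t = -0.350 * sqrt(81) / sqrt(1 - 0.1225) = -3.3622 on 81 df
        assert pearson_p_from_r(-0.350, 83) == pytest.approx(0.0011806, rel=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr_test(np.ones(10), np.arange(10.0))

    def test_t_test_identical_groups(self):
        v = np.r_[np.arange(5.0), np.arange(5.0)]
        flag = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        t, p = group_t_test(v, flag)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_t_test_power_at_unit_effect(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            a = rng.normal(1.0, 1.0, 40)
            b = rng.normal(0.0, 1.0, 40)
            _, p = group_t_test(np.r_[a, b], np.r_[np.ones(40), np.zeros(40)] > 0)
            hits += p < 0.05
        assert hits / 200 > 0.9

    def test_t_test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_t_test(np.arange(5.0), np.array([True, False, False, False, False]))

    def test_moderation_recoding_invariance(self):
        rng = np.random.default_rng(6)
        n = 80
        onset = rng.uniform(15, 30, n)
        sex01 = rng.integers(0, 2, n)
        gap = 0.5 * onset + rng.normal(size=n)
        t1 = moderation_regression(gap, onset, sex01)
        t2 = moderation_regression(gap, onset, sex01 + 1)  # 1/2 coding
        assert t1.loc["sex_x_age_of_onset", "p"] == pytest.approx(
            t2.loc["sex_x_age_of_onset", "p"], rel=1e-9
        )

    def test_moderation_detects_interaction(self):
        rng = np.random.default_rng(7)
        n = 200
        onset = rng.uniform(15, 30, n)
        sex = rng.integers(0, 2, n)
        gap = 0.8 * onset * sex + rng.normal(size=n)
        tab = moderation_regression(gap, onset, sex)
        assert tab.loc["sex_x_age_of_onset", "p"] < 1e-6

    def test_moderation_collinear_rejected(self):
        onset = np.arange(20.0)
        with pytest.raises(ValueError, match="collinear"):
            moderation_regression(np.arange(20.0), onset, np.zeros(20))
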