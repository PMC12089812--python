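"""Generator contracts: ground truth, determinism, null exchangeability."""

import dataclasses
import io as stdio

import numpy as np
import pytest
from scipy import stats

from neuronorm import atlas, synthetic
from neuronorm.synthetic import ClinicalModel, CohortSpec, TrajectorySpec

from conftest import MINI_FEATURES


def _spec(**kw):
    base = dict(
        n_subjects=50, age_range=(5.0, 80.0), sex_ratio=0.5, group="reference", seed=3
    )
    base.update(kw)
    return CohortSpec(**base)


class TestGroundTruthMean:
    def test_polynomial_arithmetic(self):
        t = TrajectorySpec(
            "f", powers=(1.0, 2.0), coefficients={"F": np.array([1.0, 2.0, 3.0])},
            noise_sd=1.0,
        )
        assert synthetic.ground_truth_mean(t, 2.0, "F") == pytest.approx(17.0)

    def test_covariate_independence_with_zero_loadings(self):
        t = TrajectorySpec(
            "f", powers=(0.0, 1.0), coefficients={"M": np.array([1.0, 0.5, -0.1])},
            noise_sd=1.0, covariate_loadings=np.zeros(3),
        )
        a = synthetic.ground_truth_mean(t, 30.0, "M", covariates=[0.0, 0.0, 0.0])
        b = synthetic.ground_truth_mean(t, 30.0, "M", covariates=[1e6, 2.5, 2000.0])
        assert a == pytest.approx(b)

    def test_nonpositive_age_rejected(self):
        t = TrajectorySpec(
            "f", powers=(0.0, 0.0), coefficients={"F": np.array([1.0, 1.0, 1.0])},
            noise_sd=1.0,
        )
        with pytest.raises(ValueError, match="positive"):
            synthetic.ground_truth_mean(t, 0.0, "F")
        with pytest.raises(ValueError):
            synthetic.ground_truth_mean(t, -3.0, "F")

    def test_smooth_on_dense_grid(self, trajectories):
        """Trajectory means are continuous: no jumps between 0.1-year steps."""
        grid = np.arange(3.0, 90.0, 0.1)
        for name in MINI_FEATURES + list(atlas.COVARIATES):
            t = trajectories[name]
            vals = synthetic.ground_truth_mean(t, grid, "F")
            scale = max(1.0, np.abs(vals).max())
            assert np.max(np.abs(np.diff(vals))) < 0.01 * scale


class TestReferenceGeneration:
    def test_zero_noise_reproduces_ground_truth(self, noiseless_trajectories):
        df = synthetic.make_reference_cohort(
            _spec(seed=9), noiseless_trajectories, features=MINI_FEATURES
        )
        cov = df[list(atlas.COVARIATES)].to_numpy()
        for f in MINI_FEATURES:
            t = noiseless_trajectories[f]
            expected = np.array(
                [
                    synthetic.ground_truth_mean(t, a, s, c)
                    for a, s, c in zip(df["age"], df["sex"], cov)
                ]
            )
            np.testing.assert_allclose(df[f].to_numpy(), expected, rtol=1e-12)

    def test_seed_determinism_byte_identical(self, mini_trajectories):
        frames = []
        for _ in range(2):
            df = synthetic.make_reference_cohort(
                _spec(seed=42), mini_trajectories, features=MINI_FEATURES
            )
            buf = stdio.StringIO()
            df.to_csv(buf, index=False)
            frames.append(buf.getvalue())
        assert frames[0] == frames[1]

    def test_uniform_age_mean(self, mini_trajectories):
        df = synthetic.make_reference_cohort(
            _spec(n_subjects=5000, age_range=(3.0, 90.0), seed=4),
            mini_trajectories,
            features=MINI_FEATURES,
        )
        # closed form: mean of U(3, 90) = 46.5; MC error ~ 25.1/sqrt(5000)
        assert df["age"].mean() == pytest.approx(46.5, abs=1.2)

    def test_missing_trajectory_names_feature(self, mini_trajectories):
        traj = dict(mini_trajectories)
        traj.pop("left_thalamus_volume")
        with pytest.raises(ValueError, match="left_thalamus_volume"):
            synthetic.make_reference_cohort(_spec(), traj, features=MINI_FEATURES)

    @pytest.mark.parametrize(
        "kw", [dict(n_subjects=0), dict(n_subjects=-5), dict(age_range=(30.0, 30.0)),
               dict(sex_ratio=1.5), dict(group="patients")]
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            _spec(**kw)


class TestStudyGeneration:
    def test_group_preconditions(self, mini_trajectories):
        with pytest.raises(ValueError, match="case"):
            synthetic.make_study_cohort(
                _spec(group="reference"), _spec(group="control", seed=5),
                mini_trajectories, features=MINI_FEATURES,
            )
        with pytest.raises(ValueError, match="control"):
            synthetic.make_study_cohort(
                _spec(group="case"), _spec(group="case", seed=5),
                mini_trajectories, features=MINI_FEATURES,
            )

    def test_effect_shift_key_validated(self, mini_trajectories):
        with pytest.raises(ValueError, match="no_such_region"):
            synthetic.make_study_cohort(
                _spec(group="case", effect_shift={"no_such_region": 1.0}),
                _spec(group="control", seed=5),
                mini_trajectories,
                features=MINI_FEATURES,
            )

    def test_chronological_age_stored_unshifted(self, mini_trajectories):
        case = _spec(group="case", seed=8, brainage_offset=-2.0,
                     age_range=(14.0, 35.0))
        ctrl = _spec(group="control", seed=9, age_range=(14.0, 35.0))
        df = synthetic.make_study_cohort(case, ctrl, mini_trajectories,
                                         features=MINI_FEATURES)
        ages = df.loc[df.group == "case", "age"]
        assert ages.between(14.0, 35.0).all()

    def test_null_configuration_exchangeable(self, trajectories):
        """No effect, no offset, matched ages: per-feature case/control KS
        tests behave like a global null."""
        case = CohortSpec(n_subjects=300, age_range=(16.0, 35.0), sex_ratio=0.5,
                          group="case", seed=31)
        ctrl = CohortSpec(n_subjects=300, age_range=(16.0, 35.0), sex_ratio=0.5,
                          group="control", seed=32)
        df = synthetic.make_study_cohort(case, ctrl, trajectories)
        feats = atlas.feature_manifest()
        pvals = [
            stats.ks_2samp(
                df.loc[df.group == "case", f], df.loc[df.group == "control", f]
            ).pvalue
            for f in feats
        ]
        assert np.mean(np.array(pvals) < 0.05) < 0.15

    def test_null_clinical_model_independent_of_features(self, mini_trajectories):
        cm = {"ymrs": ClinicalModel(intercept=5.0, weights={}, noise_sd=3.0, lower=0.0)}
        case = _spec(group="case", seed=11, n_subjects=400,
                     age_range=(14.0, 35.0), clinical_models=cm)
        ctrl = _spec(group="control", seed=12, age_range=(14.0, 35.0))
        df = synthetic.make_study_cohort(case, ctrl, mini_trajectories,
                                         features=MINI_FEATURES)
        cases = df.loc[df.group == "case"]
        for f in MINI_FEATURES:
            assert abs(np.corrcoef(cases["ymrs"], cases[f])[0, 1]) < 0.15

    def test_clinical_bounds_respected(self, mini_trajectories):
        case = dataclasses.replace(
            _spec(group="case", seed=13, n_subjects=500, age_range=(14.0, 35.0)),
            clinical_models=synthetic.default_clinical_models(),
        )
        ctrl = _spec(group="control", seed=14, age_range=(14.0, 35.0))
        df = synthetic.make_study_cohort(case, ctrl, mini_trajectories,
                                         features=MINI_FEATURES)
        cases = df.loc[df.group == "case"]
        assert (cases["ymrs"] >= 0).all() and (cases["madrs"] >= 0).all()
        assert (cases["age_of_onset"] <= cases["age"]).all()
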