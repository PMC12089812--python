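import dataclasses

import pytest

from neuronorm import atlas, synthetic

# Small feature subset spanning all three modalities and both default
# trajectory power families, for fast unit tests.
MINI_FEATURES = [
    "lh_bankssts_thickness",
    "rh_cuneus_thickness",
    "rh_insula_area",
    "left_thalamus_volume",
]


@pytest.fixture(scope="session")
def trajectories():
    return synthetic.default_trajectories()


@pytest.fixture(scope="session")
def mini_trajectories(trajectories):
    keep = set(MINI_FEATURES) | set(atlas.COVARIATES)
    return {k: v for k, v in trajectories.items() if k in keep}


@pytest.fixture(scope="session")
def noiseless_trajectories(mini_trajectories):
    return {
        k: dataclasses.replace(v, noise_sd=0.0) for k, v in mini_trajectories.items()
    }


@pytest.fixture(scope="session")
def mini_reference(mini_trajectories):
    spec = synthetic.CohortSpec(
        n_subjects=800,
        age_range=(3.0, 90.0),
        sex_ratio=0.5,
        group="reference",
        seed=21,
    )
    return synthetic.make_reference_cohort(
        spec, mini_trajectories, features=MINI_FEATURES
    )
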