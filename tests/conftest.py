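import numpy as np
import pytest

from otomorph import synthetic, vesicle_model
from otomorph.datatypes import cohort_mean

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def wt_spec():
    return synthetic.GeneratorSpec(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def wt_cohort(wt_spec):
    return synthetic.generate_wildtype_cohort(wt_spec)


@pytest.fixture(scope="session")
def wt_mean(wt_cohort):
    return cohort_mean(wt_cohort)


@pytest.fixture(scope="session")
def noiseless_series():
    spec = synthetic.GeneratorSpec(seed=FIXTURE_SEED, noise_sd_scale=0.0,
                                   n_embryos=1)
    return synthetic.generate_wildtype_cohort(spec)[0]


@pytest.fixture(scope="session")
def puncture_pairs(wt_spec):
    return [synthetic.generate_puncture_experiment(wt_spec, seed=100 + i)
            for i in range(10)]


@pytest.fixture(scope="session")
def calibrated_model():
    return vesicle_model.calibrate_wildtype()


@pytest.fixture(scope="session")
def wt_trajectory(calibrated_model):
    params, material, j_of, init = calibrated_model
    return vesicle_model.simulate(params, material, j_of, init, (30.0, 48.0))


@pytest.fixture(scope="session")
def puncture_pair_trajectories(calibrated_model):
    params, material, j_of, init = calibrated_model
    return vesicle_model.simulate_pair(params, material, j_of, init,
                                       (30.0, 48.0))
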