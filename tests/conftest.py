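import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import relmvpa as rm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp2_design():
    return rm.generate_design("exp2", seed=7)


@pytest.fixture(scope="session")
def exp1_design():
    return rm.generate_design("exp1", seed=7)


def make_dataset(
    experiment="exp2",
    seed=0,
    n_voxels=40,
    noise_sd=0.4,
    amplitude_scale=1.0,
    inversion_search=-1.0,
    n_runs=None,
    glm=False,
    **params,
):
    """Simulated single-subject dataset under the stock schedules."""
    design = rm.generate_design(experiment, seed=seed, n_runs=n_runs)
    p = rm.default_params(
        experiment,
        amplitude_scale=amplitude_scale,
        inversion_search=inversion_search,
        n_voxels=n_voxels,
        noise_sd=noise_sd,
        seed=seed,
        **params,
    )
    sim = rm.simulate_bold_and_glm if glm else rm.simulate_t_patterns
    return sim(design, p)


@pytest.fixture(scope="session")
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def strong_exp2_dataset():
    """High-SNR dataset: decoding should be essentially perfect at active TRs."""
    return make_dataset("exp2", seed=11, n_voxels=40, noise_sd=1e-3)
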