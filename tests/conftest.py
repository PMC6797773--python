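import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from isoseed import ACTINIDIA_OKUTAMA_2013, DispersalEstimate, default_study_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def line():
    """Published Actinidia calibration constants."""
    return ACTINIDIA_OKUTAMA_2013


@pytest.fixture
def small_study():
    """Four-species scenario scaled down for unit tests."""
    return dataclasses.replace(default_study_config(), n_seeds_per_species=5, rng_seed=42)


def make_estimate(
    distance=0.0,
    ci=(-100.0, 100.0),
    species="Asian black bear",
    seed_id="s0",
    mother_alt=1000.0,
    sd=50.0,
    rhat=1.0,
    extrapolated=False,
):
    """Hand-built DispersalEstimate for classification/regression tests."""
    return DispersalEstimate(
        seed_id=seed_id,
        species=species,
        post_mean_mother_alt=mother_alt,
        post_mean_distance=distance,
        post_sd=sd,
        ci95=ci,
        rhat=rhat,
        extrapolated=extrapolated,
    )
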