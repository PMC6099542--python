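import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from petkin import (
    KineticParameters,
    build_aif,
    default_frame_schedule,
)
from petkin.metabolism import default_brain_pf_model, default_plasma_pf_model
from petkin.synthetic import AifParams, generate_aif

K4_FIXED = 0.05

#: Published whole-brain group means (control / LPS).
CONTROL_MEANS = dict(K1=0.58, k2=0.35, ratio=0.34, Kb=0.53)
LPS_MEANS = dict(K1=0.86, k2=0.36, ratio=0.61, Kb=0.68)


def params_from_means(means, k4=K4_FIXED, vB=0.05):
    return KineticParameters(
        K1=means["K1"], k2=means["k2"], k3=means["ratio"] * k4, k4=k4, Kb=means["Kb"], vB=vB
    )


@pytest.fixture(scope="session")
def plasma_pf():
    return default_plasma_pf_model()


@pytest.fixture(scope="session")
def brain_pf():
    return default_brain_pf_model()


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def plasma_samples():
    return generate_aif(AifParams())


@pytest.fixture(scope="session")
def aif(plasma_samples, plasma_pf):
    return build_aif(plasma_samples, plasma_pf)


@pytest.fixture(scope="session")
def control_params():
    return params_from_means(CONTROL_MEANS)


@pytest.fixture(scope="session")
def lps_params():
    return params_from_means(LPS_MEANS)


def random_params(rng, vB=0.05):
    """One plausible random parameter draw (shared by property tests)."""
    return KineticParameters(
        K1=rng.uniform(0.2, 1.2),
        k2=rng.uniform(0.1, 0.6),
        k3=rng.uniform(0.05, 1.5) * K4_FIXED,
        k4=K4_FIXED,
        Kb=rng.uniform(0.1, 1.0),
        vB=vB,
    )
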