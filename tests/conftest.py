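import numpy as np
import pytest

from enerloop.energy_model import EnergyStateModel, HarmonicCoefficients
from enerloop.virtual_patient import (
    CortisolParams,
    make_cohort_presets,
    sample_pulse_train,
    simulate_cortisol,
)


@pytest.fixture(scope="session")
def presets():
    return make_cohort_presets()


@pytest.fixture(scope="session")
def default_model() -> EnergyStateModel:
    """A well-conditioned reference model used across decoder tests.

    The harmonic drive is scaled so that, after the 1/(1-rho) gain of the
    state recursion, the circadian swing stays within a few state units and
    the two envelope channels never cross.
    """
    return EnergyStateModel(
        rho=0.98,
        sigma_eps2=0.05,
        harmonic=HarmonicCoefficients(
            alpha1=0.04, alpha2=0.01, beta1=-0.03, beta2=0.005
        ),
        gamma0=-3.0,
        gamma1=0.8,
        r0=14.0,
        r1=1.0,
        sigma_v2=1.0,
        s0=4.0,
        s1=0.6,
        sigma_w2=0.8,
    )


@pytest.fixture(scope="session")
def healthy_profile(presets):
    """Two simulated days of the healthy cohort (session-cached)."""
    pulses = sample_pulse_train(presets["healthy"], 2 * 1440, seed=11)
    profile = simulate_cortisol(pulses, CortisolParams(), 2, seed=12)
    return pulses, profile
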