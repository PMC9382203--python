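import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoramp.pipeline import analyze_trial
from thermoramp.protocol import RampProtocol
from thermoramp.synthgen import CohortConfig, PopulationVariation, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("suite")


def make_small_protocol(**overrides) -> RampProtocol:
    """A short two-step protocol (fast ramps) for cheap trace-level tests."""
    kwargs = dict(
        start_temp=10.0,
        step_targets=(15.0, 20.0),
        ramp_rates=(20.0, 20.0),
        plateau_duration=12.0,
        cycles_per_plateau=2,
        closed_phase=2.0,
        flush_phase=5.0,
        blood_sample_temps=(10.0, 20.0),
    )
    kwargs.update(overrides)
    return RampProtocol(**kwargs)


@pytest.fixture(scope="session")
def small_protocol() -> RampProtocol:
    return make_small_protocol()


def zero_noise_config(**overrides) -> CohortConfig:
    kwargs = dict(
        n_per_group=1,
        seed=5,
        protocol=make_small_protocol(),
        o2_noise_sd_pct=0.0,
        flow_noise_frac=0.0,
        blood_noise_cv=0.0,
        variation=PopulationVariation(mo2_cv=0.0, sv_cv=0.0, hr_cv=0.0, mass_sd_kg=0.0),
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two fish per group on the short protocol, default noise."""
    return generate_cohort(CohortConfig(n_per_group=2, seed=3, protocol=make_small_protocol()))


@pytest.fixture(scope="session")
def default_cohort():
    """The full study conditions: n=9 per arm, full ramp, default noise."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Respirometry + cardiac stage outputs for every fish of the cohort."""
    return [analyze_trial(t) for t in default_cohort.trials]
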