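import pytest
from hypothesis import settings

from crutchload import SessionConfig, WalkProfile, load_pilot_fixture, simulate_walk

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config100():
    """The worked-example prescription: 100 kg subject, 50 % ideal load."""
    return SessionConfig(body_weight=100.0)


@pytest.fixture(scope="session")
def fixture_df():
    return load_pilot_fixture()


@pytest.fixture(scope="session")
def clean_profile():
    """Deterministic, noiseless, perfectly compliant 10-stride walk."""
    return WalkProfile(noise_sd=0.0, target_pct_sd=0.0, left_share_sd=0.0,
                       asynchrony_ms_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_walk(clean_profile, config100):
    return simulate_walk(clean_profile, config100)
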