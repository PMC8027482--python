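"""Shared fixtures: protocol specs and cached synthetic trials.

Trials are session-scoped because generation (especially the 200-Hz marker
streams) dominates test runtime; tests must not mutate them.
"""

import pytest

from skimass import protocol, synthesize


@pytest.fixture(scope="session")
def spec():
    return protocol.build_protocol()


@pytest.fixture(scope="session")
def short_spec():
    return protocol.build_protocol({"laps": 2})


@pytest.fixture(scope="session")
def zero_noise():
    return synthesize.NoiseConfig.zero()


@pytest.fixture(scope="session")
def clean_trial(short_spec, zero_noise):
    """Two-lap noiseless trial with force/marker streams."""
    profile = synthesize.SkierProfile(
        seed=5, tte=45.0, pole_fraction=0.60, pole_left_share=0.55
    )
    streams, truth = synthesize.generate_trial(
        short_spec, profile, noise=zero_noise,
        include_familiarization=False, include_markers=True,
    )
    return profile, streams, truth


@pytest.fixture(scope="session")
def noisy_trial(spec):
    """Full seven-lap trial at default noise, one break, no markers."""
    profile = synthesize.SkierProfile(seed=11, tte=90.0, break_times=(400.0,))
    streams, truth = synthesize.generate_trial(
        spec, profile, include_familiarization=False, include_markers=False
    )
    return profile, streams, truth
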