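import numpy as np
import pytest

from gaitconverge.simulate import (Bout, DayScript, GaitProfile,
                                   default_day_script,
                                   default_walker_profile,
                                   simulate_recording_day)


@pytest.fixture(scope="session")
def walker_day():
    """One default walker recording day with ground truth (seeded)."""
    profile = default_walker_profile()
    script = default_day_script(seed=42, day_index=1)
    streams, truth = simulate_recording_day(profile, script)
    return profile, script, streams, truth


@pytest.fixture(scope="session")
def noiseless_bout():
    """A single noise- and jitter-free 60 s walk bout."""
    profile = GaitProfile(stride_duration_mean_aff=1.4,
                          stride_duration_mean_nonaff=1.4,
                          stride_duration_sd=0.0, noise_sd=0.0)
    script = DayScript([Bout("walk", 60.0)], seed=0)
    streams, truth = simulate_recording_day(profile, script)
    return profile, streams, truth


def by_role(streams, placement, role):
    for s in streams:
        if s.placement == placement and s.role == role:
            return s
    raise AssertionError(f"missing {placement}/{role}")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
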