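import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

import sealight as sl

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return sl.OceanTruth()


@pytest.fixture(scope="session")
def small_deployment(truth):
    """One seal, 3 spring days, default generator settings."""
    spec = sl.DeploymentSpec("test01", dt.date(2002, 11, 1), n_days=3, seed=7)
    track = sl.generate_track(spec, truth)
    return sl.generate_dive_series(spec, track, truth), track, spec


def piecewise_profile(knee_depth, surface_value, slope_below,
                      max_depth=350.0, step=5.0, noise_sd=0.0, rng=None):
    """Two-segment profile: constant to the knee, linear gradient below."""
    depth = np.arange(0.0, max_depth + step, step)
    value = np.where(depth <= knee_depth, surface_value,
                     surface_value + slope_below * (depth - knee_depth))
    if noise_sd and rng is not None:
        value = value + rng.normal(0.0, noise_sd, len(depth))
    return depth, value
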