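import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tailbalance as tb
from tailbalance.biomech import TiltProfile

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, dropout-free no-tilt trial (deterministic)."""
    cfg = tb.SimConfig(ridge_width=8.0, noise_sd=0.0, dropout_rate=0.0,
                       seed=7)
    return tb.simulate_trial(cfg)


@pytest.fixture(scope="session")
def il_tilt_trial():
    """Left-tail, left-tilt (ipsilateral) trial at realistic noise."""
    cfg = tb.SimConfig(ridge_width=4.0, tail_side="left",
                       tilt=TiltProfile(20.0, 0.19, "left", 360), seed=11)
    return tb.simulate_trial(cfg)


@pytest.fixture
def small_table():
    """Two-bodypart, ten-frame keypoint table with clean likelihoods."""
    rng = np.random.default_rng(3)
    import pandas as pd
    cols = pd.MultiIndex.from_product(
        [["scorer0"], ["nose", "tail_base"], ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"])
    data = np.column_stack([
        rng.uniform(0, 100, 10), rng.uniform(0, 100, 10), np.ones(10),
        rng.uniform(0, 100, 10), rng.uniform(0, 100, 10), np.ones(10),
    ])
    return tb.KeypointTable(pd.DataFrame(data, columns=cols), view="top")
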