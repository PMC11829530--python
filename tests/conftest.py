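import dataclasses

import numpy as np
import pytest

from saccadekit.geometry import ScreenGeometry
from saccadekit.simulate import BehaviorProfile


@pytest.fixture
def geom():
    return ScreenGeometry()


@pytest.fixture
def default_profile():
    return BehaviorProfile()


@pytest.fixture
def clean_profile():
    """Noiseless, error-free, exclusion-free behaviour with unit gain."""
    return dataclasses.replace(
        BehaviorProfile(),
        noise_sd_deg=0.0, blink_rate_per_min=0.0, gain_mean=1.0, gain_sd=0.0,
        anticipation_prob=0.0, prosaccade_error_prob=0.0,
        antisaccade_uncorrected_prob=0.0, antisaccade_corrected_prob=0.0,
        mg_inhibitory_prob=0.0, mg_directional_prob=0.0,
        excl_probs_saccade=(0.0, 0.0, 0.0), excl_probs_memory=(0.0, 0.0, 0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
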