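import numpy as np
import pytest

from wristbp import BeatSeries, Site, simulate_cohort


@pytest.fixture
def constant_window() -> BeatSeries:
    """A 1-minute beat window with constant 120/80 pressures."""
    return BeatSeries(Site.RADIAL, np.arange(7) * 10.0, np.full(7, 120.0), np.full(7, 80.0))


@pytest.fixture
def profile():
    return simulate_cohort(1, seed=42)[0]


@pytest.fixture
def cohort20():
    return simulate_cohort(20, seed=7)
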