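import numpy as np
import pytest

from tactrf import montage, trf
from tactrf.synth import SimulationConfig


@pytest.fixture(scope="session")
def lags() -> trf.LagWindow:
    return trf.LagWindow()


@pytest.fixture(scope="session")
def focal_left() -> np.ndarray:
    """Indices of the left-central focal set (right-hand stimulation)."""
    return montage.channel_index(list(montage.LEFT_CENTRAL))


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small design for fast integration tests: 3 subjects, 1-min trials."""
    return SimulationConfig(
        n_subjects=3, conditions=("right_thumb", "control"),
        trials_per_condition=2, trial_minutes=1.0, seed=7,
    )
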