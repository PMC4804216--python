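import numpy as np
import pytest

from bgcircuit import load_default_model
from bgcircuit.network import SimulationTrace
from bgcircuit.task import StimulusSchedule


@pytest.fixture(scope="session")
def default_config():
    return load_default_model()


@pytest.fixture
def one_trial_schedule():
    """A single 20-s trial of four contiguous 5-s patterns."""
    vals = np.array([
        [0.5, 0.45, 0.4, 0.35],
        [0.35, 0.5, 0.45, 0.4],
        [0.4, 0.35, 0.5, 0.45],
        [0.45, 0.4, 0.35, 0.5],
    ])
    return StimulusSchedule(onsets=np.arange(4) * 5.0, offsets=np.arange(1, 5) * 5.0,
                            values=vals, trial_id=np.zeros(4, dtype=int))


def make_trace(y_cortex: np.ndarray, dt: float = 0.01) -> SimulationTrace:
    """Wrap a (n, 4) cortical activity array as a SimulationTrace."""
    n = y_cortex.shape[0]
    return SimulationTrace(t=(np.arange(n) + 1) * dt, y=np.asarray(y_cortex, float),
                           slices={"cortex": slice(0, 4)})
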