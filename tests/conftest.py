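import numpy as np
import pytest

from solecop.geometry import default_layout
from solecop.preprocess import preprocess
from solecop.segment import crop_steady_state, segment_steps
from solecop.simulate import GaitSimConfig, simulate_recording


@pytest.fixture(scope="session")
def layout():
    return default_layout("left")


@pytest.fixture(scope="session")
def sim_recording(layout):
    """Seeded 10-step recording, preprocessed."""
    cfg = GaitSimConfig(n_steps=10, seed=42)
    return preprocess(simulate_recording(cfg, layout))


@pytest.fixture(scope="session")
def sim_phases(sim_recording, layout):
    return crop_steady_state(segment_steps(sim_recording, layout))


def make_recording(frames, sample_rate=100.0, **kw):
    """Helper: wrap a (T, 16) array (or (T, n) padded with zeros)."""
    from solecop.preprocess import PressureRecording

    frames = np.asarray(frames, dtype=float)
    if frames.shape[1] < 16:
        pad = np.zeros((frames.shape[0], 16 - frames.shape[1]))
        frames = np.hstack([frames, pad])
    return PressureRecording(sample_rate=sample_rate, frames=frames, **kw)
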