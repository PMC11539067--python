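import warnings

import numpy as np
import pytest

from finwave.propulsion import PRESETS
from finwave.synthetic import render_frames
from finwave.tracking import track_stack
from finwave.wave_model import generate_bending_field, midlines_from_bending


@pytest.fixture(scope="session")
def flexible_params():
    return PRESETS["flexible"]


@pytest.fixture(scope="session")
def flexible_field(flexible_params):
    return generate_bending_field(flexible_params, duration_s=4.0, fps=200.0)


@pytest.fixture(scope="session")
def flexible_sequence(flexible_params, flexible_field):
    return midlines_from_bending(flexible_field, flexible_params)


@pytest.fixture(scope="session")
def rendered_clip(flexible_sequence):
    """Short rendered video of the flexible preset plus its tracking
    output, shared across tests (rendering + tracking dominate runtime)."""
    frames, masks = render_frames(flexible_sequence, px_per_mm=6.0, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seq, traj, qc = track_stack(frames, fps=200.0, scale_px_per_mm=6.0)
    return {
        "frames": frames,
        "masks": masks,
        "true_seq": flexible_sequence,
        "tracked_seq": seq,
        "trajectory": traj,
        "qc": qc,
        "px_per_mm": 6.0,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
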