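import numpy as np
import pytest

from larva_etho.io_formats import Experiment, TrackRecord


def make_straight_track(
    larva_id="L0",
    duration=20.0,
    fps=15.0,
    velocity=(1.0, 0.0),
    body_length=4.0,
    start=(0.0, 0.0),
    with_spine=True,
):
    """Track moving at constant velocity with a straight spine along the
    direction of motion (or along x if stationary)."""
    times = np.arange(0.0, duration, 1.0 / fps)
    v = np.asarray(velocity, dtype=float)
    centroid = np.asarray(start, dtype=float) + times[:, None] * v
    spine = None
    if with_spine:
        u = v / np.linalg.norm(v) if np.linalg.norm(v) > 0 else np.array([1.0, 0.0])
        offsets = (np.linspace(0, body_length, 11) - body_length / 2)[:, None] * u
        spine = centroid[:, None, :] + offsets[None, :, :]
    return TrackRecord(larva_id=larva_id, times=times, centroid=centroid, spine=spine)


@pytest.fixture
def straight_track():
    return make_straight_track()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_experiment():
    tracks = {
        "A": make_straight_track("A", duration=20.0, velocity=(0.5, 0.0)),
        "B": make_straight_track("B", duration=12.0, velocity=(0.0, 0.4), start=(5.0, 5.0)),
    }
    return Experiment(tracks=tracks, stimulus_onset=10.0, stimulus_duration=1.0)
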