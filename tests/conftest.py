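import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from sensorprune import (
    Frame,
    GaitSimConfig,
    SensorRecording,
    clean,
    paper_like_fixture,
    simulate_recording,
    slice_frames,
)

TRUTH_GROUPS = (("1", "2", "6"), ("3", "4", "5", "7", "8", "9", "10"))


@pytest.fixture
def small_recording():
    readings = np.array(
        [
            [1.0, 2.0, 3.0],
            [4.0, 5.0, 6.0],
            [7.0, 8.0, 9.0],
            [10.0, 11.0, 12.0],
        ]
    )
    return SensorRecording(
        sensor_labels=("s1", "s2", "s3"),
        readings=readings,
        sampling_rate=100.0,
        reading_range=(0.0, 64.0),
    )


@pytest.fixture
def fixture_recording():
    return clean(paper_like_fixture(0))


@pytest.fixture
def fixture_frames(fixture_recording):
    return slice_frames(fixture_recording, 500)


def noise_free_two_group(seed: int = 0, phase_b: float = 0.35) -> SensorRecording:
    """Two well-separated groups, no noise, unit gains: within-group series
    are bitwise identical by construction."""
    cfg = GaitSimConfig(
        n_sensors=6,
        group_assignment=(0, 0, 0, 1, 1, 1),
        group_amplitude={0: 30.0, 1: 50.0},
        group_baseline={0: 2.0, 1: 4.0},
        group_phase={0: 0.0, 1: phase_b},
        noise_sd=0.0,
        seed=seed,
    )
    return simulate_recording(cfg)


@pytest.fixture
def noise_free_frames():
    return slice_frames(noise_free_two_group(), 500)


def make_frame(data: np.ndarray, labels=None) -> Frame:
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(str(i + 1) for i in range(data.shape[1]))
    return Frame(source="test", start_index=0, data=data, sensor_labels=labels)
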