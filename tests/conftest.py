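import numpy as np
import pytest

from gaitdtw import PipelineConfig, lowpass_filter
from gaitdtw.event_detection import detect_events
from gaitdtw.synthetic import GaitParams, synth_foot


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def normal_foot(cfg):
    """Default-parameter normal-gait recording with its ground truth."""
    rec, truth = synth_foot(GaitParams(seed=42))
    return rec, truth


@pytest.fixture(scope="session")
def quiet_foot(cfg):
    """Low-noise recording for sample-accurate event comparisons."""
    rec, truth = synth_foot(
        GaitParams(seed=7, gyro_noise_sd=0.05, pressure_noise_sd=0.005)
    )
    return rec, truth


@pytest.fixture(scope="session")
def detected(normal_foot, cfg):
    rec, truth = normal_foot
    filtered = lowpass_filter(rec, cfg)
    return filtered, detect_events(filtered, cfg), truth


def event_sample_errors(rec, ev_indices, truth_times, rate):
    """Signed detected-minus-planted offsets in samples."""
    detected_t = rec.time[np.asarray(ev_indices, dtype=int)]
    k = min(len(detected_t), len(truth_times))
    return (detected_t[:k] - np.asarray(truth_times)[:k]) * rate
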