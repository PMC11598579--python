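import numpy as np
import pytest

from gaitcx import (correct_orientation_and_gravity, detect_heel_contacts,
                    lowpass_filter, resample_uniform)
from gaitcx.synthetic import generate_isi, generate_recording


def preprocess_streams(accel, invert=True):
    """Standard preprocessing: resample, gravity/orientation, low-pass."""
    sig = resample_uniform(accel)
    sig = correct_orientation_and_gravity(sig, invert=invert)
    return sig, lowpass_filter(sig)


def detect_on(accel, invert=True):
    """Run the full detection chain; returns (filtered, raw) event series."""
    sig, sig_f = preprocess_streams(accel, invert=invert)
    return detect_heel_contacts(sig, sig_f)


def match_stats(detected_times, true_times, tol=0.030):
    """(recall, precision) of detected events against ground truth."""
    detected_times = np.asarray(detected_times)
    true_times = np.asarray(true_times)
    if detected_times.size == 0:
        return 0.0, 0.0
    recall = np.mean([np.min(np.abs(detected_times - t)) <= tol
                      for t in true_times])
    precision = np.mean([np.min(np.abs(true_times - d)) <= tol
                         for d in detected_times])
    return float(recall), float(precision)


@pytest.fixture(scope="session")
def clean_recording():
    """30 identical 1.1 s strides, no jitter/noise, gravity, inverted."""
    isi = generate_isi("white", 30, mean_s=1.1, sd_s=0.0, seed=0)
    return generate_recording([isi], timestamp_jitter_sd=0.0, noise_sd=0.0,
                              gravity=9.81, invert=True, seed=0)
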