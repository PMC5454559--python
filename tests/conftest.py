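import numpy as np
import pytest

import insolegait as ig


@pytest.fixture
def config():
    return ig.PipelineConfig()


@pytest.fixture
def quiet_profile():
    """Noise-free 60 s session at cadence 90, perfect heel strikes."""
    return ig.GaitProfile(cadence=90.0, duration_s=60.0, noise_sd=0.0, seed=7)


@pytest.fixture
def quiet_recording(quiet_profile):
    return ig.simulate_recording(quiet_profile)


def mask_to_recording(mask, sample_rate=100.0):
    """Recording whose left-foot contact mask equals `mask` (sensor 1 at 200)."""
    mask = np.asarray(mask, dtype=bool)
    frames = np.zeros((mask.size, 16), dtype=np.int64)
    frames[mask, 0] = 200
    return ig.PressureRecording(
        participant_id="t", session_timestamp=__import__("datetime").datetime(2020, 1, 1),
        affected_side="left", frames=frames, sample_rate=sample_rate)


def rle_oracle(mask, sample_rate, min_contact_ms, max_gap_ms):
    """Brute-force scan: runs of True, merge short gaps, drop short runs.

    Independent pure-Python reimplementation of the segmentation contract,
    used only to check the vectorised detector.
    """
    ms = 1000.0 / sample_rate
    runs = []
    start = None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append([start, i])
            start = None
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) * ms < max_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if (e - s) * ms >= min_contact_ms]
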