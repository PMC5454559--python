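"""Step segmentation against a brute-force run-length oracle, plus invariants."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import insolegait as ig
from insolegait.errors import ValidationError

from conftest import mask_to_recording, rle_oracle


class TestContactMask:
    def test_all_zero_frames_all_false(self):
        rec = mask_to_recording(np.zeros(50, dtype=bool))
        assert not ig.contact_mask(rec, "left", 15.0).any()

    def test_constant_high_sensor_all_true(self):
        rec = mask_to_recording(np.ones(50, dtype=bool))
        assert ig.contact_mask(rec, "left", 20.0).all()

    def test_matches_per_sample_max_oracle(self):
        rng = np.random.default_rng(4)
        frames = rng.integers(0, 256, size=(300, 16))
        rec = ig.PressureRecording(
            participant_id="t",
            session_timestamp=__import__("datetime").datetime(2020, 1, 1),
            affected_side="left", frames=frames)
        for foot, cols in (("left", slice(0, 8)), ("right", slice(8, 16))):
            expected = np.array([max(row) >= 120 for row in frames[:, cols]])
            np.testing.assert_array_equal(
                ig.contact_mask(rec, foot, 120.0), expected)

    def test_invalid_threshold(self):
        rec = mask_to_recording(np.ones(10, dtype=bool))
        with pytest.raises(ValidationError):
            ig.contact_mask(rec, "left", 0.0)


class TestDetectSteps:
    def test_all_zero_recording_no_steps(self, config):
        rec = mask_to_recording(np.zeros(500, dtype=bool))
        assert ig.detect_steps(rec, "left", config) == []

    def test_square_wave_five_bursts(self, config):
        # five 600 ms bursts separated by 400 ms silences
        mask = np.tile(np.r_[np.ones(60, bool), np.zeros(40, bool)], 5)
        steps = ig.detect_steps(mask_to_recording(mask), "left", config)
        assert len(steps) == 5
        assert all(s.contact_ms == 600.0 for s in steps)

    def test_short_gap_is_merged(self, config):
        mask = np.r_[np.ones(30, bool), np.zeros(3, bool), np.ones(30, bool)]
        cfg = replace(config, max_gap_ms=50.0)
        steps = ig.detect_steps(mask_to_recording(mask), "left", cfg)
        assert len(steps) == 1
        assert steps[0].contact_ms == 630.0

    def test_negative_durations_rejected(self):
        with pytest.raises(ValidationError):
            ig.PipelineConfig(min_contact_ms=-1.0)
        with pytest.raises(ValidationError):
            ig.PipelineConfig(max_gap_ms=-1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.booleans(), max_size=400),
           st.sampled_from([50.0, 150.0, 300.0]),
           st.sampled_from([0.0, 30.0, 60.0, 120.0]))
    def test_equals_rle_oracle(self, mask, min_contact_ms, max_gap_ms):
        mask = np.asarray(mask, dtype=bool)
        cfg = ig.PipelineConfig(min_contact_ms=min_contact_ms, max_gap_ms=max_gap_ms)
        steps = ig.detect_steps(mask_to_recording(mask), "left", cfg)
        expected = rle_oracle(mask, 100.0, min_contact_ms, max_gap_ms)
        assert [(s.start_index, s.end_index) for s in steps] == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_step_count_monotone_in_threshold_on_separated_bumps(self, seed):
        # unimodal bursts separated by >= max_gap silence: raising the
        # threshold can only shrink or drop a burst, never split one
        rng = np.random.default_rng(seed)
        pieces = [np.zeros(10)]
        for _ in range(rng.integers(1, 8)):
            width = int(rng.integers(5, 60))
            amp = float(rng.uniform(30, 255))
            pieces.append(amp * np.sin(np.pi * np.arange(width) / max(width - 1, 1)))
            pieces.append(np.zeros(int(rng.integers(10, 40))))
        signal = np.clip(np.rint(np.concatenate(pieces)), 0, 255).astype(np.int64)
        frames = np.zeros((signal.size, 16), dtype=np.int64)
        frames[:, 0] = signal
        rec = ig.PressureRecording(
            participant_id="t",
            session_timestamp=__import__("datetime").datetime(2020, 1, 1),
            affected_side="left", frames=frames)
        counts_thr = [len(ig.detect_steps(rec, "left",
                          ig.PipelineConfig(threshold=t, min_contact_ms=50)))
                      for t in (10.0, 40.0, 80.0, 160.0)]
        assert counts_thr == sorted(counts_thr, reverse=True)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_step_count_monotone_in_min_contact(self, seed):
        rng = np.random.default_rng(seed)
        frames = np.zeros((400, 16), dtype=np.int64)
        frames[:, 0] = np.clip(rng.normal(40, 60, 400), 0, 255).astype(np.int64)
        rec = ig.PressureRecording(
            participant_id="t",
            session_timestamp=__import__("datetime").datetime(2020, 1, 1),
            affected_side="left", frames=frames)
        counts_mc = [len(ig.detect_steps(rec, "left",
                         ig.PipelineConfig(min_contact_ms=mc)))
                     for mc in (0.0, 50.0, 150.0, 400.0)]
        assert counts_mc == sorted(counts_mc, reverse=True)

    def test_concatenation_with_long_silence_concatenates_steps(self, config):
        mask_a = np.r_[np.ones(40, bool), np.zeros(30, bool), np.ones(40, bool)]
        mask_b = np.r_[np.ones(25, bool), np.zeros(50, bool), np.ones(60, bool)]
        silence = np.zeros(int(config.max_gap_ms / 10) + 2, dtype=bool)
        steps_a = ig.detect_steps(mask_to_recording(mask_a), "left", config)
        steps_b = ig.detect_steps(mask_to_recording(mask_b), "left", config)
        combined = ig.detect_steps(
            mask_to_recording(np.r_[mask_a, silence, mask_b]), "left", config)
        offset = mask_a.size + silence.size
        expected = [(s.start_index, s.end_index) for s in steps_a] + \
                   [(s.start_index + offset, s.end_index + offset) for s in steps_b]
        assert [(s.start_index, s.end_index) for s in combined] == expected

    def test_boundary_truncated_contact_kept_and_flagged(self, config):
        mask = np.r_[np.ones(20, bool), np.zeros(60, bool), np.ones(20, bool)]
        steps = ig.detect_steps(mask_to_recording(mask), "left", config)
        assert len(steps) == 2
        assert all(s.truncated for s in steps)

    def test_steps_disjoint_and_ordered_on_simulated_gait(self, quiet_recording, config):
        for foot in ("left", "right"):
            steps = ig.detect_steps(quiet_recording, foot, config)
            assert steps
            for a, b in zip(steps, steps[1:]):
                assert a.end_index <= b.start_index
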