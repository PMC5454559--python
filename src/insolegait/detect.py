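"""Step segmentation: turn a foot's pressure time series into step objects.

The detector scans the per-sample contact mask (any non-excluded sensor at or
above the contact threshold), merges sub-threshold gaps shorter than
``max_gap_ms`` (mid-stance dropouts), discards runs shorter than
``min_contact_ms`` (sensor bounce), and emits each surviving run as a
:class:`StepObject` — one contiguous ground-contact episode of one foot.
Contacts truncated by the recording boundary are kept if long enough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import ValidationError
from .io import PressureRecording, SensorLayout


@dataclass(frozen=True)
class StepObject:
    """One contiguous ground-contact episode of one foot.

    ``slice`` is the (n, 8) raw sub-matrix for samples in the half-open index
    window [start_index, end_index); columns follow the foot layout's sensor
    order.  ``onset_sensor_ids`` are the sensors at or above the contact
    threshold within the onset window after first contact.
    """

    foot: str
    start_index: int
    end_index: int
    sample_rate: float
    slice: np.ndarray
    threshold: float
    onset_sensor_ids: frozenset[int] = frozenset()
    excluded_sensor_ids: frozenset[int] = frozenset()
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValidationError("step must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def start_ms(self) -> float:
        return self.start_index * 1000.0 / self.sample_rate

    @property
    def end_ms(self) -> float:
        return self.end_index * 1000.0 / self.sample_rate

    @property
    def contact_ms(self) -> float:
        return self.end_ms - self.start_ms


def contact_mask(recording: PressureRecording, foot: str, threshold: float,
                 exclude_sensor_ids: frozenset[int] | set[int] = frozenset()) -> np.ndarray:
    """Boolean per-sample series: some non-excluded sensor >= threshold."""
    if not 0 < threshold <= 255:
        raise ValidationError("threshold must lie in (0, 255]")
    frames = recording.foot_frames(foot)
    layout = recording.layout(foot)
    cols = [j for j, s in enumerate(layout.sensors)
            if s.sensor_id not in exclude_sensor_ids]
    if not cols:
        return np.zeros(frames.shape[0], dtype=bool)
    return frames[:, cols].max(axis=1) >= threshold


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    edges = np.flatnonzero(np.diff(m))
    starts = list(edges[m[edges] == 0] + 1)
    ends = list(edges[m[edges] == 1] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def merge_and_filter_runs(runs: list[tuple[int, int]], sample_rate: float,
                          min_contact_ms: float, max_gap_ms: float) -> list[tuple[int, int]]:
    """Merge runs separated by gaps < max_gap_ms, then drop runs < min_contact_ms."""
    ms_per_sample = 1000.0 / sample_rate
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and (start - merged[-1][1]) * ms_per_sample < max_gap_ms:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if (e - s) * ms_per_sample >= min_contact_ms]


def detect_steps(recording: PressureRecording, foot: str,
                 config: PipelineConfig | None = None,
                 exclude_sensor_ids: frozenset[int] | set[int] = frozenset()
                 ) -> list[StepObject]:
    """Segment one foot's series into chronological step objects."""
    config = config or PipelineConfig()
    mask = contact_mask(recording, foot, config.threshold, exclude_sensor_ids)
    runs = merge_and_filter_runs(_mask_runs(mask), recording.sample_rate,
                                 config.min_contact_ms, config.max_gap_ms)
    frames = recording.foot_frames(foot)
    layout = recording.layout(foot)
    onset_n = max(1, math.ceil(config.onset_window_ms * recording.sample_rate / 1000.0))
    excluded = frozenset(exclude_sensor_ids)
    steps = []
    for start, end in runs:
        window = frames[start:min(start + onset_n, end)]
        active = window.max(axis=0) >= config.threshold
        onset_ids = frozenset(
            s.sensor_id for j, s in enumerate(layout.sensors)
            if active[j] and s.sensor_id not in excluded
        )
        steps.append(StepObject(
            foot=foot,
            start_index=int(start),
            end_index=int(end),
            sample_rate=recording.sample_rate,
            slice=frames[start:end],
            threshold=config.threshold,
            onset_sensor_ids=onset_ids,
            excluded_sensor_ids=excluded,
            truncated=(start == 0 and mask[0]) or (end == mask.size and mask[-1]),
        ))
    return steps
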