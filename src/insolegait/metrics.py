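"""Session-level rehabilitation metrics.

Aggregates the per-step outputs of one walking session into the quantities fed
back to participants:

* **speed** — both feet's step count per minute of recording;
* **heel-strike percentage** per side — share of that foot's steps classified
  heel-initiated (rehabilitation goal: 100% on the affected side);
* **symmetry (balance)** — the affected foot's share of total loading, in
  percent (goal: 50%, ideal bilateral symmetry).  Default loading measure is
  the pressure-time integral; stance-time share is the config alternative.

Faulty-sensor handling: stuck/saturated/flatlined sensors are detected first;
for the symmetry calculation each faulty sensor id is removed from BOTH feet
(the matching process with the opposite foot), so a dead sensor cannot bias the
balance estimate.  Step counting and heel-strike classification exclude only a
foot's own faulty sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .detect import StepObject, detect_steps
from .errors import DegenerateInputError, UndefinedMetricError
from .features import classify_heel_strike
from .io import PressureRecording, SensorLayout, RAW_MAX


@dataclass(frozen=True)
class FaultySensor:
    foot: str
    sensor_id: int
    mode: str  # stuck_zero | stuck_max | flatline


@dataclass(frozen=True)
class SessionMetrics:
    duration_s: float
    n_steps_affected: int
    n_steps_nonaffected: int
    speed: float  # steps/min, both feet
    heel_strike_pct_affected: float | None
    heel_strike_pct_nonaffected: float | None
    symmetry_pct: float | None
    faulty_sensors: tuple[FaultySensor, ...] = ()
    excluded_pairs: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "n_steps_affected": self.n_steps_affected,
            "n_steps_nonaffected": self.n_steps_nonaffected,
            "speed": self.speed,
            "heel_strike_pct_affected": self.heel_strike_pct_affected,
            "heel_strike_pct_nonaffected": self.heel_strike_pct_nonaffected,
            "symmetry_pct": self.symmetry_pct,
            "faulty_sensors": [
                {"foot": f.foot, "sensor_id": f.sensor_id, "mode": f.mode}
                for f in self.faulty_sensors
            ],
            "excluded_pairs": list(self.excluded_pairs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMetrics":
        return cls(
            duration_s=d["duration_s"],
            n_steps_affected=d["n_steps_affected"],
            n_steps_nonaffected=d["n_steps_nonaffected"],
            speed=d["speed"],
            heel_strike_pct_affected=d["heel_strike_pct_affected"],
            heel_strike_pct_nonaffected=d["heel_strike_pct_nonaffected"],
            symmetry_pct=d["symmetry_pct"],
            faulty_sensors=tuple(FaultySensor(**f) for f in d.get("faulty_sensors", [])),
            excluded_pairs=tuple(d.get("excluded_pairs", [])),
        )


def detect_faulty_sensors(recording: PressureRecording,
                          config: PipelineConfig | None = None) -> list[FaultySensor]:
    """Flag stuck, saturated, and flatlined sensors.

    A sensor is faulty iff (a) it is constant at 0 across every contact episode
    of its foot while at least one other sensor is active in every episode
    (stuck low), (b) it is constant at the 8-bit ceiling for the entire
    recording (saturated), or (c) its whole-recording value range is below
    ``range_epsilon`` while the foot has at least one detected step (flatline).
    A foot with no detected steps is unjudgeable: its sensors are left
    unflagged rather than declared faulty.
    """
    config = config or PipelineConfig()
    faulty: list[FaultySensor] = []
    for foot in ("left", "right"):
        frames = recording.foot_frames(foot)
        layout = recording.layout(foot)
        if frames.shape[0] == 0:
            continue
        saturated = {
            s.sensor_id
            for j, s in enumerate(layout.sensors)
            if np.all(frames[:, j] == RAW_MAX)
        }
        for sid in sorted(saturated):
            faulty.append(FaultySensor(foot, sid, "stuck_max"))
        # Steps judged with saturated sensors removed (they force an all-true mask).
        steps = detect_steps(recording, foot, config, exclude_sensor_ids=saturated)
        if not steps:
            continue
        for j, s in enumerate(layout.sensors):
            if s.sensor_id in saturated:
                continue
            stuck_low = all(
                np.all(st.slice[:, j] == 0)
                and (np.delete(st.slice, j, axis=1) >= config.threshold).any()
                for st in steps
            )
            if stuck_low:
                faulty.append(FaultySensor(foot, s.sensor_id, "stuck_zero"))
            elif np.ptp(frames[:, j]) < config.range_epsilon:
                faulty.append(FaultySensor(foot, s.sensor_id, "flatline"))
    return faulty


def _loading_integral(steps: Sequence[StepObject], layout: SensorLayout,
                      excluded: frozenset[int], mode: str) -> float:
    """Pressure-time integral (or total contact time) over non-excluded sensors."""
    if mode == "contact_time":
        return float(sum(st.contact_ms for st in steps))
    cols = [j for j, s in enumerate(layout.sensors) if s.sensor_id not in excluded]
    if not cols:
        raise UndefinedMetricError("all sensors excluded; loading undefined")
    total = 0.0
    for st in steps:
        total += float(layout.calibration.apply(st.slice[:, cols]).sum()) / st.sample_rate
    return total


def compute_symmetry(steps_affected: Sequence[StepObject],
                     steps_nonaffected: Sequence[StepObject],
                     layout_affected: SensorLayout,
                     layout_nonaffected: SensorLayout,
                     faulty: Sequence[FaultySensor] = (),
                     mode: str = "integral") -> float:
    """Affected-foot share of total loading, in percent.

    Each faulty sensor id is excluded from both feet — the matching process
    that keeps a dead sensor from biasing the balance estimate.
    """
    excluded = frozenset(f.sensor_id for f in faulty)
    i_aff = _loading_integral(steps_affected, layout_affected, excluded, mode)
    i_non = _loading_integral(steps_nonaffected, layout_nonaffected, excluded, mode)
    if i_aff + i_non == 0:
        raise UndefinedMetricError("no loading on either foot; symmetry undefined")
    return 100.0 * i_aff / (i_aff + i_non)


def _heel_pct(steps: Sequence[StepObject], layout: SensorLayout,
              onset_window_ms: float) -> float | None:
    if not steps:
        return None
    n_heel = sum(classify_heel_strike(st, layout, onset_window_ms) for st in steps)
    return 100.0 * n_heel / len(steps)


def compute_session_metrics(recording: PressureRecording,
                            config: PipelineConfig | None = None) -> SessionMetrics:
    """Full per-session aggregation: faults -> steps -> features -> metrics."""
    config = config or PipelineConfig()
    if recording.duration_s == 0:
        raise DegenerateInputError("zero-duration recording")

    faulty = detect_faulty_sensors(recording, config)
    own_faults = {
        foot: frozenset(f.sensor_id for f in faulty if f.foot == foot)
        for foot in ("left", "right")
    }
    pairs = frozenset(f.sensor_id for f in faulty)

    aff, non = recording.affected_side, recording.nonaffected_side
    steps = {
        foot: detect_steps(recording, foot, config,
                           exclude_sensor_ids=own_faults[foot])
        for foot in ("left", "right")
    }

    # Symmetry uses a paired-exclusion detection pass so that both feet are
    # judged through identical sensor subsets end to end.
    if pairs:
        sym_steps = {
            foot: detect_steps(recording, foot, config, exclude_sensor_ids=pairs)
            for foot in ("left", "right")
        }
    else:
        sym_steps = steps
    try:
        symmetry = compute_symmetry(
            sym_steps[aff], sym_steps[non],
            recording.layout(aff), recording.layout(non),
            faulty, mode=config.symmetry_mode,
        )
    except UndefinedMetricError:
        symmetry = None

    n_aff, n_non = len(steps[aff]), len(steps[non])
    return SessionMetrics(
        duration_s=recording.duration_s,
        n_steps_affected=n_aff,
        n_steps_nonaffected=n_non,
        speed=(n_aff + n_non) / (recording.duration_s / 60.0),
        heel_strike_pct_affected=_heel_pct(steps[aff], recording.layout(aff),
                                           config.onset_window_ms),
        heel_strike_pct_nonaffected=_heel_pct(steps[non], recording.layout(non),
                                              config.onset_window_ms),
        symmetry_pct=symmetry,
        faulty_sensors=tuple(faulty),
        excluded_pairs=tuple(sorted(pairs)),
    )
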