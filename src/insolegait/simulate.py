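"""Synthetic hemiparetic-gait generator.

Emulates what an 8-sensor-per-foot, 100 Hz, 8-bit plantar-pressure insole
records during a walking session: alternating left/right stance episodes at a
set cadence, heel-to-toe pressure progression within each stance, per-step
Bernoulli heel-strike success (a failed draw models drop-foot: heel sensors
stay silent and contact initiates at the forefoot), left/right loading
asymmetry, stuck-sensor faults, and additive sensor noise.

The per-sensor stance envelope is a half-sine bump over a region-specific
sub-window of stance: heel sensors are active in the first 60% of stance, toe
sensors in the last 60%, midfoot/metatarsal in the middle 80%.  Feet are
phase-offset by half a cycle, so double support occurs whenever the stance
fraction exceeds one half.  Loading asymmetry is imposed exactly: after the
noise-free envelopes are built, per-foot amplitudes are scaled so the affected
foot carries precisely ``load_share_affected`` of the total pressure-time
integral (before noise, faults, and 8-bit quantisation).

Same seed + same profile => bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .errors import DegenerateInputError, ValidationError
from .io import (N_SENSORS, RAW_MAX, PressureRecording, SensorLayout,
                 default_layout)

#: fraction of stance during which each region's sensors are loaded
_REGION_WINDOWS = {
    "heel": (0.0, 0.6),
    "midfoot": (0.1, 0.9),
    "metatarsal": (0.1, 0.9),
    "toe": (0.4, 1.0),
}


@dataclass(frozen=True)
class GaitProfile:
    """Ground-truth walking parameters for one simulated session."""

    cadence: float = 90.0              # steps/min, both feet combined
    stance_fraction: float = 0.6       # fraction of a foot's cycle in contact
    heel_strike_prob_left: float = 1.0
    heel_strike_prob_right: float = 1.0
    load_share_affected: float = 0.5   # affected foot's share of total loading
    affected_side: str = "left"
    peak_pressure: float = 180.0       # raw-count amplitude of the loaded foot
    noise_sd: float = 2.0              # additive Gaussian noise, raw counts
    fault_spec: tuple[tuple[str, int, str], ...] = ()  # (foot, sensor_id, mode)
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValidationError("cadence must be > 0")
        if not 0 < self.stance_fraction < 1:
            raise ValidationError("stance_fraction must lie in (0, 1)")
        for name in ("heel_strike_prob_left", "heel_strike_prob_right",
                     "load_share_affected"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.affected_side not in ("left", "right"):
            raise ValidationError("affected_side must be 'left' or 'right'")
        if not 0 < self.peak_pressure <= RAW_MAX:
            raise ValidationError(f"peak_pressure must lie in (0, {RAW_MAX}]")
        if self.noise_sd < 0 or self.duration_s < 0:
            raise ValidationError("noise_sd and duration_s must be >= 0")
        for foot, sid, mode in self.fault_spec:
            if foot not in ("left", "right") or not 1 <= sid <= N_SENSORS \
                    or mode not in ("stuck_zero", "stuck_max"):
                raise ValidationError(f"bad fault spec entry {(foot, sid, mode)}")

    def heel_strike_prob(self, foot: str) -> float:
        return self.heel_strike_prob_left if foot == "left" else self.heel_strike_prob_right


@dataclass(frozen=True)
class StepTruth:
    foot: str
    start_index: int
    end_index: int
    heel_strike: bool


@dataclass(frozen=True)
class GroundTruth:
    profile: GaitProfile
    steps: tuple[StepTruth, ...]

    def steps_for(self, foot: str) -> tuple[StepTruth, ...]:
        return tuple(s for s in self.steps if s.foot == foot)


def _stance_onsets(n_samples: int, stance_samples: int, cycle_samples: float,
                   phase_samples: float) -> list[int]:
    """Start indices of complete stances fitting inside the recording."""
    onsets = []
    k = 0
    while True:
        start = int(round(phase_samples + k * cycle_samples))
        if start + stance_samples > n_samples:
            break
        onsets.append(start)
        k += 1
    return onsets


def _foot_envelope(n_samples: int, onsets: Sequence[int], stance_samples: int,
                   layout: SensorLayout, heel_draws: Sequence[bool]) -> np.ndarray:
    """Unit-amplitude (n_samples, 8) envelope with heel-to-toe progression."""
    env = np.zeros((n_samples, N_SENSORS))
    t = np.arange(stance_samples) / max(stance_samples - 1, 1)  # 0..1 within stance
    for onset, heel_ok in zip(onsets, heel_draws):
        for j, sensor in enumerate(layout.sensors):
            if sensor.region == "heel" and not heel_ok:
                continue  # drop-foot: contact initiates at the forefoot
            w0, w1 = _REGION_WINDOWS[sensor.region]
            inside = (t >= w0) & (t <= w1)
            bump = np.zeros(stance_samples)
            bump[inside] = np.sin(np.pi * (t[inside] - w0) / (w1 - w0))
            env[onset:onset + stance_samples, j] += bump
    return env


def simulate_with_truth(profile: GaitProfile) -> tuple[PressureRecording, GroundTruth]:
    """Generate one session and its per-step ground truth."""
    fs = 100.0
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration_s * fs))
    layouts = {"left": default_layout("left"), "right": default_layout("right")}

    cycle = 120.0 / profile.cadence * fs          # per-foot cycle, samples
    stance = max(int(round(profile.stance_fraction * cycle)), 1)
    truths: list[StepTruth] = []
    envelopes: dict[str, np.ndarray] = {}
    if n > 0:
        for foot, phase in (("left", 0.0), ("right", cycle / 2.0)):
            onsets = _stance_onsets(n, stance, cycle, phase)
            if not onsets:
                raise DegenerateInputError(
                    f"duration {profile.duration_s}s too short for one full "
                    f"step at cadence {profile.cadence}"
                )
            draws = rng.random(len(onsets)) < profile.heel_strike_prob(foot)
            truths.extend(
                StepTruth(foot, o, o + stance, bool(d))
                for o, d in zip(onsets, draws)
            )
            envelopes[foot] = _foot_envelope(n, onsets, stance, layouts[foot], draws)
    else:
        envelopes = {f: np.zeros((0, N_SENSORS)) for f in ("left", "right")}

    aff = profile.affected_side
    non = "right" if aff == "left" else "left"
    if n > 0:
        j_aff = envelopes[aff].sum()
        j_non = envelopes[non].sum()
        s = profile.load_share_affected
        # amplitude ratio enforcing the exact loading share of the integrals
        if s == 0 or j_aff == 0:
            amp = {aff: 0.0, non: profile.peak_pressure}
        elif s == 1 or j_non == 0:
            amp = {aff: profile.peak_pressure, non: 0.0}
        else:
            ratio = (s / (1 - s)) * (j_non / j_aff)
            if ratio >= 1:
                amp = {aff: profile.peak_pressure, non: profile.peak_pressure / ratio}
            else:
                amp = {aff: profile.peak_pressure * ratio, non: profile.peak_pressure}
    else:
        amp = {aff: 0.0, non: 0.0}

    frames = np.concatenate(
        [envelopes["left"] * amp["left"], envelopes["right"] * amp["right"]],
        axis=1,
    )
    if profile.noise_sd > 0 and n > 0:
        frames = frames + rng.normal(0.0, profile.noise_sd, frames.shape)
    for foot, sid, mode in profile.fault_spec:
        col = (0 if foot == "left" else N_SENSORS) + (sid - 1)
        frames[:, col] = 0.0 if mode == "stuck_zero" else RAW_MAX
    frames = np.clip(np.rint(frames), 0, RAW_MAX).astype(np.int64)

    recording = PressureRecording(
        participant_id="sim",
        session_timestamp=datetime(2020, 1, 1),
        affected_side=aff,
        frames=frames,
        sample_rate=fs,
        layout_left=layouts["left"],
        layout_right=layouts["right"],
    )
    truths.sort(key=lambda st: st.start_index)
    return recording, GroundTruth(profile=profile, steps=tuple(truths))


def simulate_recording(profile: GaitProfile) -> PressureRecording:
    """Generate one synthetic walking session."""
    return simulate_with_truth(profile)[0]


@dataclass(frozen=True)
class TrendSpec:
    """Longitudinal scenario: per-parameter linear drift across sessions."""

    n_sessions: int
    session_dates: tuple[date, ...]
    profile_start: GaitProfile
    profile_end: GaitProfile

    def __post_init__(self) -> None:
        if self.n_sessions < 2:
            raise ValidationError("a trend needs at least 2 sessions")
        if len(self.session_dates) != self.n_sessions:
            raise ValidationError("session_dates length must equal n_sessions")
        dates = list(self.session_dates)
        if len(set(dates)) != len(dates):
            raise ValidationError("duplicate session dates")
        if dates != sorted(dates):
            raise ValidationError("session dates must be strictly increasing")
        if self.profile_start.affected_side != self.profile_end.affected_side:
            raise ValidationError("affected_side must not change within a trend")

    def profile_at(self, i: int) -> GaitProfile:
        """Per-parameter linear interpolation; session-indexed seed."""
        f = i / (self.n_sessions - 1)
        a, b = self.profile_start, self.profile_end

        def lerp(name: str) -> float:
            return getattr(a, name) + f * (getattr(b, name) - getattr(a, name))

        return replace(
            a,
            cadence=lerp("cadence"),
            stance_fraction=lerp("stance_fraction"),
            heel_strike_prob_left=lerp("heel_strike_prob_left"),
            heel_strike_prob_right=lerp("heel_strike_prob_right"),
            load_share_affected=lerp("load_share_affected"),
            peak_pressure=lerp("peak_pressure"),
            noise_sd=lerp("noise_sd"),
            duration_s=lerp("duration_s"),
            seed=(a.seed + i) % (2**31),
        )


def simulate_sessions(trend: TrendSpec) -> list[tuple[date, PressureRecording]]:
    """One recording per session date, generated from the interpolated profile."""
    out = []
    for i, d in enumerate(trend.session_dates):
        rec = simulate_recording(trend.profile_at(i))
        rec = replace(rec, session_timestamp=datetime.combine(d, time(12, 0)))
        out.append((d, rec))
    return out


def simulate_participant(trend: TrendSpec, participant_id: str = "sim",
                         config: PipelineConfig | None = None):
    """Simulate a participant's history and analyse every session.

    Returns a :class:`~insolegait.cohort.ParticipantRecord` whose sessions carry
    computed :class:`~insolegait.metrics.SessionMetrics`.
    """
    from .cohort import ParticipantRecord
    from .metrics import compute_session_metrics

    config = config or PipelineConfig()
    sessions = [
        (d, compute_session_metrics(rec, config))
        for d, rec in simulate_sessions(trend)
    ]
    return ParticipantRecord(
        participant_id=participant_id,
        affected_side=trend.profile_start.affected_side,
        sessions=tuple(sessions),
    )
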