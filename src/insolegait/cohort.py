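"""Longitudinal cohort analysis: chronological half-split comparison.

Each participant's sessions are split into a first (baseline) and second half
in chronological order; per-metric half means are contrasted into a delta
("relative score"), and deltas are averaged across the cohort.  Metrics:
heel-strike percentage on the affected and nonaffected sides, balance
(symmetry percentage), and speed (steps/min).  Default delta conventions:
percentage-point difference for metrics already on a percent scale, relative
percent change for speed.  Compliance (session frequency) and intensity (walk
length) trends are reported per half as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UndefinedMetricError
from .metrics import SessionMetrics

METRICS = ("heel_affected", "heel_nonaffected", "balance", "speed")

_METRIC_FIELDS = {
    "heel_affected": "heel_strike_pct_affected",
    "heel_nonaffected": "heel_strike_pct_nonaffected",
    "balance": "symmetry_pct",
    "speed": "speed",
}

_DELTA_COLUMNS = {
    "heel_affected": "heel_affected_pct",
    "heel_nonaffected": "heel_nonaffected_pct",
    "balance": "balance_pct",
    "speed": "speed_pct",
}


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics plus chronologically ordered analysed sessions."""

    participant_id: str
    affected_side: str
    sessions: tuple[tuple[date, SessionMetrics], ...]
    age: int | None = None
    time_since_stroke_months: int | None = None
    computer_experience: str | None = None
    walking_aid: str | None = None

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.sessions]
        if dates != sorted(dates):
            raise DegenerateInputError("sessions must be in chronological order")


@dataclass(frozen=True)
class MetricDelta:
    first_mean: float | None
    second_mean: float | None
    delta: float | None


@dataclass(frozen=True)
class HalfSplitResult:
    participant_id: str
    metrics: dict[str, MetricDelta]
    n_first: int
    n_second: int


@dataclass(frozen=True)
class UsageTrend:
    """Compliance (sessions/day) and intensity (mean walk length) per half."""

    participant_id: str
    frequency_first: float
    frequency_second: float
    intensity_first: float
    intensity_second: float

    @property
    def frequency_change(self) -> float:
        return self.frequency_second - self.frequency_first

    @property
    def intensity_change(self) -> float:
        return self.intensity_second - self.intensity_first


@dataclass(frozen=True)
class CohortSummary:
    rows: pd.DataFrame                    # per-participant delta table
    means: dict[str, float]               # per-metric cohort mean delta, 1 dp
    improving: dict[str, int]             # participants with delta > 0

    def to_dict(self) -> dict:
        return {
            "rows": self.rows.to_dict(orient="records"),
            "means": self.means,
            "improving": self.improving,
        }


def split_halves(sessions: Sequence) -> tuple[list, list]:
    """Chronological half-split; odd counts put the extra session first."""
    n = len(sessions)
    if n < 2:
        raise DegenerateInputError(f"need >= 2 sessions to split, got {n}")
    k = math.ceil(n / 2)
    return list(sessions[:k]), list(sessions[k:])


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def compute_deltas(first: Sequence[SessionMetrics],
                   second: Sequence[SessionMetrics],
                   participant_id: str = "",
                   speed_delta: str = "relative",
                   pct_delta: str = "difference") -> HalfSplitResult:
    """Contrast first- and second-half session metrics into relative scores.

    Missing per-session metrics (feet with zero steps, undefined symmetry) are
    excluded from the half means rather than treated as zero.
    """
    if not first or not second:
        raise DegenerateInputError("both halves must be non-empty")
    out: dict[str, MetricDelta] = {}
    for metric, attr in _METRIC_FIELDS.items():
        m1 = _mean_or_none([getattr(s, attr) for s in first
                            if getattr(s, attr) is not None])
        m2 = _mean_or_none([getattr(s, attr) for s in second
                            if getattr(s, attr) is not None])
        if m1 is None or m2 is None:
            out[metric] = MetricDelta(m1, m2, None)
            continue
        relative = speed_delta == "relative" if metric == "speed" \
            else pct_delta == "relative"
        if relative:
            if m1 == 0:
                raise UndefinedMetricError(
                    f"first-half mean {metric} is 0; relative change undefined")
            delta = 100.0 * (m2 - m1) / m1
        else:
            delta = m2 - m1
        out[metric] = MetricDelta(m1, m2, delta)
    return HalfSplitResult(participant_id=participant_id, metrics=out,
                           n_first=len(first), n_second=len(second))


def half_split_participant(participant: ParticipantRecord,
                           speed_delta: str = "relative",
                           pct_delta: str = "difference") -> HalfSplitResult:
    first, second = split_halves(participant.sessions)
    return compute_deltas([m for _, m in first], [m for _, m in second],
                          participant_id=participant.participant_id,
                          speed_delta=speed_delta, pct_delta=pct_delta)


def summarize_delta_table(rows: pd.DataFrame) -> CohortSummary:
    """Cohort statistics from a per-participant delta table.

    ``rows`` must carry ``participant_id`` plus the four delta columns
    (``heel_affected_pct``, ``heel_nonaffected_pct``, ``balance_pct``,
    ``speed_pct``).  Means are reported to one decimal; the improvement count
    per metric is the number of participants with a strictly positive delta.
    """
    means = {}
    improving = {}
    for metric, col in _DELTA_COLUMNS.items():
        vals = rows[col].dropna()
        means[metric] = round(float(vals.mean()), 1) if len(vals) else float("nan")
        improving[metric] = int((vals > 0).sum())
    return CohortSummary(rows=rows.reset_index(drop=True), means=means,
                         improving=improving)


def summarize_cohort(participants: Sequence[ParticipantRecord],
                     speed_delta: str = "relative",
                     pct_delta: str = "difference") -> CohortSummary:
    """Half-split every participant and average the deltas across the cohort."""
    if not participants:
        raise DegenerateInputError("empty cohort")
    records = []
    for p in participants:
        hs = half_split_participant(p, speed_delta=speed_delta, pct_delta=pct_delta)
        records.append(
            {"participant_id": hs.participant_id,
             **{col: hs.metrics[m].delta for m, col in _DELTA_COLUMNS.items()}}
        )
    return summarize_delta_table(pd.DataFrame.from_records(records))


def participant_to_dict(p: ParticipantRecord) -> dict:
    return {
        "participant_id": p.participant_id,
        "affected_side": p.affected_side,
        "age": p.age,
        "time_since_stroke_months": p.time_since_stroke_months,
        "computer_experience": p.computer_experience,
        "walking_aid": p.walking_aid,
        "sessions": [
            {"date": d.isoformat(), "metrics": m.to_dict()}
            for d, m in p.sessions
        ],
    }


def participant_from_dict(d: dict) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=d["participant_id"],
        affected_side=d["affected_side"],
        age=d.get("age"),
        time_since_stroke_months=d.get("time_since_stroke_months"),
        computer_experience=d.get("computer_experience"),
        walking_aid=d.get("walking_aid"),
        sessions=tuple(
            (date.fromisoformat(s["date"]), SessionMetrics.from_dict(s["metrics"]))
            for s in d["sessions"]
        ),
    )


def usage_trends(participants: Sequence[ParticipantRecord]) -> list[UsageTrend]:
    """Per-half compliance (sessions/elapsed day) and intensity (mean walk s)."""
    out = []
    for p in participants:
        first, second = split_halves(p.sessions)
        halves = []
        for half in (first, second):
            dates = [d for d, _ in half]
            elapsed = max((dates[-1] - dates[0]).days + 1, 1)
            halves.append((
                len(half) / elapsed,
                float(np.mean([m.duration_s for _, m in half])),
            ))
        out.append(UsageTrend(
            participant_id=p.participant_id,
            frequency_first=halves[0][0], frequency_second=halves[1][0],
            intensity_first=halves[0][1], intensity_second=halves[1][1],
        ))
    return out
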