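"""Reading and writing insole recordings, sensor layouts, and packaged cohort tables.

A raw recording is a two-foot, 8-sensor-per-foot matrix of 8-bit pressure counts
sampled at a fixed rate (100 Hz on the target hardware).  On disk it is a CSV
with a ``# key: value`` metadata header block followed by one row per sample
(columns ``sample,L1..L8,R1..R8``).  Sensor layouts — the mapping from sensor id
to anatomical region plus an affine raw-count -> kg/cm^2 calibration — travel as
JSON.  The demographics and per-participant performance tables from the source
study ship as small packaged CSV fixtures.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

Side = Literal["left", "right"]
Region = Literal["heel", "midfoot", "metatarsal", "toe"]

REGIONS: tuple[str, ...] = ("heel", "midfoot", "metatarsal", "toe")
N_SENSORS = 8
RAW_MAX = 255

_HEADER_KEYS = ("participant_id", "session_timestamp", "affected_side", "sample_rate")


@dataclass(frozen=True)
class Calibration:
    """Affine map from raw 8-bit counts to pressure in kg/cm^2.

    ``pressure = scale * raw + offset``.  The identity map is the default; the
    hardware's calibration curve is device-specific configuration.  ``scale``
    must be non-negative so the map is monotone non-decreasing over [0, 255].
    """

    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValidationError("calibration scale must be >= 0 (monotone map)")

    def apply(self, raw):
        return self.scale * np.asarray(raw, dtype=float) + self.offset


@dataclass(frozen=True)
class SensorSpec:
    sensor_id: int
    region: str
    position_label: str = ""

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )


@dataclass(frozen=True)
class SensorLayout:
    """Anatomical assignment of one foot's eight force-sensitive resistors.

    Column ``j`` of that foot's pressure matrix carries ``sensors[j]``.
    """

    side: str
    sensors: tuple[SensorSpec, ...]
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if len(self.sensors) != N_SENSORS:
            raise ValidationError(f"expected {N_SENSORS} sensors, got {len(self.sensors)}")
        ids = [s.sensor_id for s in self.sensors]
        if len(set(ids)) != N_SENSORS:
            raise ValidationError(f"sensor ids must be unique, got {ids}")
        regions = {s.region for s in self.sensors}
        if "heel" not in regions or "toe" not in regions:
            raise ValidationError("layout needs at least one heel and one toe sensor")

    @property
    def sensor_ids(self) -> tuple[int, ...]:
        return tuple(s.sensor_id for s in self.sensors)

    def region_sensor_ids(self, region: str) -> frozenset[int]:
        return frozenset(s.sensor_id for s in self.sensors if s.region == region)

    def columns_for_ids(self, ids: Iterable[int]) -> list[int]:
        wanted = set(ids)
        return [j for j, s in enumerate(self.sensors) if s.sensor_id in wanted]

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "sensors": [
                {"sensor_id": s.sensor_id, "region": s.region,
                 "position_label": s.position_label}
                for s in self.sensors
            ],
            "calibration": {"scale": self.calibration.scale,
                            "offset": self.calibration.offset},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorLayout":
        cal = d.get("calibration", {})
        return cls(
            side=d["side"],
            sensors=tuple(
                SensorSpec(int(s["sensor_id"]), s["region"], s.get("position_label", ""))
                for s in d["sensors"]
            ),
            calibration=Calibration(float(cal.get("scale", 1.0)),
                                    float(cal.get("offset", 0.0))),
        )


#: Default region assignment: two heel sensors under the calcaneus, one midfoot,
#: three across the metatarsal heads, two under the hallux/toes.  This is
#: configuration (a typical placement), not hardware-fixed anatomy.
_DEFAULT_REGIONS = ("heel", "heel", "midfoot", "metatarsal",
                    "metatarsal", "metatarsal", "toe", "toe")


def default_layout(side: str, calibration: Calibration | None = None) -> SensorLayout:
    """A typical 8-sensor heel-to-toe layout for one foot."""
    return SensorLayout(
        side=side,
        sensors=tuple(
            SensorSpec(i + 1, region, f"{side[0].upper()}{i + 1}")
            for i, region in enumerate(_DEFAULT_REGIONS)
        ),
        calibration=calibration or Calibration(),
    )


def read_layout(path: str | Path) -> SensorLayout:
    with open(path) as fh:
        return SensorLayout.from_dict(json.load(fh))


def write_layout(layout: SensorLayout, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(layout.to_dict(), indent=2) + "\n")
    return path


@dataclass(frozen=True)
class PressureRecording:
    """One walking session's raw two-foot pressure matrix plus metadata.

    ``frames`` has shape (n_samples, 16): columns 0..7 are the left foot
    (L1..L8), columns 8..15 the right foot (R1..R8), integer counts in
    [0, 255].  Sample ``i`` occurs at ``i * 1000 / sample_rate`` ms.
    """

    participant_id: str
    session_timestamp: datetime
    affected_side: str
    frames: np.ndarray
    sample_rate: float = 100.0
    layout_left: SensorLayout = field(default_factory=lambda: default_layout("left"))
    layout_right: SensorLayout = field(default_factory=lambda: default_layout("right"))

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValidationError(
                f"affected_side must be 'left' or 'right', got {self.affected_side!r}"
            )
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        frames = np.asarray(self.frames)
        if frames.size == 0:
            frames = frames.reshape(0, 2 * N_SENSORS)
        if frames.ndim != 2 or frames.shape[1] != 2 * N_SENSORS:
            raise ValidationError(
                f"frames must have {2 * N_SENSORS} columns, got shape {frames.shape}"
            )
        if not np.issubdtype(frames.dtype, np.integer):
            if not np.all(np.equal(np.mod(frames, 1), 0)):
                raise ValidationError("raw counts must be integers")
            frames = frames.astype(np.int64)
        if frames.size and (frames.min() < 0 or frames.max() > RAW_MAX):
            raise ValidationError(f"raw counts must lie in [0, {RAW_MAX}]")
        object.__setattr__(self, "frames", frames)

    @property
    def n_samples(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def nonaffected_side(self) -> str:
        return "right" if self.affected_side == "left" else "left"

    def foot_frames(self, foot: str) -> np.ndarray:
        """The (n_samples, 8) sub-matrix for one foot."""
        if foot == "left":
            return self.frames[:, :N_SENSORS]
        if foot == "right":
            return self.frames[:, N_SENSORS:]
        raise ValidationError(f"foot must be 'left' or 'right', got {foot!r}")

    def layout(self, foot: str) -> SensorLayout:
        return self.layout_left if foot == "left" else self.layout_right

    def with_frames(self, frames: np.ndarray) -> "PressureRecording":
        return replace(self, frames=frames)


def _column_names() -> list[str]:
    return [f"L{i}" for i in range(1, N_SENSORS + 1)] + \
           [f"R{i}" for i in range(1, N_SENSORS + 1)]


def read_recording(path: str | Path,
                   layout_left: SensorLayout | None = None,
                   layout_right: SensorLayout | None = None) -> PressureRecording:
    """Parse a recording CSV (``# key: value`` header block + sample rows)."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        body_start = i + 1
        stripped = line.lstrip("#").strip()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            meta[key.strip()] = value.strip()
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise ParseError(f"{path}: missing header keys {missing}")

    expected_cols = 1 + 2 * N_SENSORS
    for offset, line in enumerate(lines[body_start:]):
        if line.strip() and line.count(",") != expected_cols - 1:
            raise ParseError(
                f"{path}: line {body_start + offset + 1} has "
                f"{line.count(',') + 1} columns, expected {expected_cols}"
            )

    body = "".join(lines[body_start:])
    table = pd.read_csv(_stdio.StringIO(body))
    cols = _column_names()
    if list(table.columns) != ["sample"] + cols:
        raise ParseError(f"{path}: unexpected column header {list(table.columns)}")
    frames = table[cols].to_numpy()
    try:
        return PressureRecording(
            participant_id=meta["participant_id"],
            session_timestamp=datetime.fromisoformat(meta["session_timestamp"]),
            affected_side=meta["affected_side"],
            sample_rate=float(meta["sample_rate"]),
            frames=frames,
            layout_left=layout_left or default_layout("left"),
            layout_right=layout_right or default_layout("right"),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_recording(recording: PressureRecording, path: str | Path) -> Path:
    """Emit the CSV dialect read by :func:`read_recording` (lossless round-trip)."""
    path = Path(path)
    header = (
        f"# participant_id: {recording.participant_id}\n"
        f"# session_timestamp: {recording.session_timestamp.isoformat()}\n"
        f"# affected_side: {recording.affected_side}\n"
        f"# sample_rate: {recording.sample_rate:g}\n"
    )
    table = pd.DataFrame(recording.frames, columns=_column_names())
    table.insert(0, "sample", np.arange(recording.n_samples))
    with open(path, "w", newline="") as fh:
        fh.write(header)
        table.to_csv(fh, index=False)
    return path


def load_cohort_fixture(name: str) -> pd.DataFrame:
    """Load a packaged cohort table.

    ``"table1"`` — participant demographics (age, affected side, time since
    stroke, computer experience, walking aid).  ``"table5"`` — per-participant
    first-vs-second-half relative scores: heel-strike change on the affected and
    nonaffected sides, balance (symmetry) change, and speed change, in percent.
    """
    if name not in ("table1", "table5"):
        raise KeyError(f"unknown cohort fixture {name!r}; expected 'table1' or 'table5'")
    ref = resources.files("insolegait.data") / f"{name}.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, keep_default_na=False, na_values=[])
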