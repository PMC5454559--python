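"""Per-step gait features: heel strike, toe off, contact time, average pressure.

These are the low-level events derived from each step object: the time and
sensor location of first ground contact (heel strike) and last contact (toe
off), the overall contact duration, and the mean calibrated pressure across the
entire foot during contact.  A step is classified heel-initiated iff a
heel-region sensor is above the contact threshold within a short onset window
after first contact — in hemiparetic gait, drop-foot produces forefoot-initiated
contacts that fail this test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import StepObject
from .errors import ConfigurationError, UndefinedMetricError
from .io import SensorLayout

DEFAULT_ONSET_WINDOW_MS = 50.0


@dataclass(frozen=True)
class StepFeatures:
    heel_strike_ms: float
    heel_strike_sensor_id: int
    toe_off_ms: float
    toe_off_sensor_id: int
    contact_ms: float
    avg_pressure: float  # kg/cm^2 after calibration
    heel_initiated: bool


def _edge_sensor(values: np.ndarray, layout: SensorLayout,
                 active_cols: list[int], threshold: float) -> int:
    """Sensor id carrying the contact at a boundary sample.

    The above-threshold sensor with the maximal value; ties broken by lowest
    sensor id; falls back to the overall argmax if none reaches threshold
    (possible at merged-gap boundaries).
    """
    candidates = [j for j in active_cols if values[j] >= threshold] or active_cols
    best = max(candidates,
               key=lambda j: (values[j], -layout.sensors[j].sensor_id))
    return layout.sensors[best].sensor_id


def classify_heel_strike(step: StepObject, layout: SensorLayout,
                         onset_window_ms: float = DEFAULT_ONSET_WINDOW_MS) -> bool:
    """True iff a heel-region sensor is above threshold in the onset window."""
    if onset_window_ms <= 0:
        raise ConfigurationError("onset_window_ms must be > 0")
    heel_ids = layout.region_sensor_ids("heel") - step.excluded_sensor_ids
    if not layout.region_sensor_ids("heel"):
        raise ConfigurationError("layout has no heel-region sensor")
    if not heel_ids:
        return False
    n = max(1, math.ceil(onset_window_ms * step.sample_rate / 1000.0))
    window = step.slice[:min(n, step.n_samples)]
    cols = layout.columns_for_ids(heel_ids)
    return bool((window[:, cols] >= step.threshold).any())


def extract_features(step: StepObject, layout: SensorLayout,
                     onset_window_ms: float = DEFAULT_ONSET_WINDOW_MS) -> StepFeatures:
    """Derive the per-step feature set from one step object."""
    active_cols = [j for j, s in enumerate(layout.sensors)
                   if s.sensor_id not in step.excluded_sensor_ids]
    if not active_cols:
        raise UndefinedMetricError("all sensors excluded as faulty; features undefined")
    first = np.asarray(step.slice[0], dtype=float)
    last = np.asarray(step.slice[-1], dtype=float)
    calibrated = layout.calibration.apply(step.slice[:, active_cols])
    return StepFeatures(
        heel_strike_ms=step.start_ms,
        heel_strike_sensor_id=_edge_sensor(first, layout, active_cols, step.threshold),
        toe_off_ms=step.end_ms,
        toe_off_sensor_id=_edge_sensor(last, layout, active_cols, step.threshold),
        contact_ms=step.contact_ms,
        avg_pressure=float(calibrated.mean()),
        heel_initiated=classify_heel_strike(step, layout, onset_window_ms),
    )
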