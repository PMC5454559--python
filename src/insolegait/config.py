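"""Pipeline configuration.

Every constant the analysis needs but the hardware does not fix lives here,
with its default and rationale:

* ``threshold`` (raw counts, default 15 ≈ 6% of the 8-bit full scale): contact
  threshold on the per-sample max across a foot's sensors — above FSR idle
  noise, far below stance loading.
* ``min_contact_ms`` (default 150): contacts shorter than this are sensor
  bounce, not stance; stance even at fast cadence exceeds 150 ms.
* ``max_gap_ms`` (default 60): sub-threshold gaps shorter than this inside a
  stance (mid-stance dropouts) are merged rather than splitting the step.
* ``onset_window_ms`` (default 50): a step counts as heel-initiated iff a
  heel-region sensor is above threshold within this window after first contact.
* ``symmetry_mode``: ``"integral"`` (pressure-time integral share, default) or
  ``"contact_time"`` (stance-time share).
* ``speed_delta`` / ``pct_delta``: half-split delta conventions — relative
  percent change for speed, percentage-point difference for metrics already on
  a percent scale.
* ``range_epsilon`` (raw counts, default 3): a sensor whose whole-recording
  range is below this while the foot is stepping is flagged as flatlined.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = 15.0
    min_contact_ms: float = 150.0
    max_gap_ms: float = 60.0
    onset_window_ms: float = 50.0
    symmetry_mode: str = "integral"
    speed_delta: str = "relative"
    pct_delta: str = "difference"
    range_epsilon: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 255:
            raise ValidationError("threshold must lie in (0, 255]")
        for name in ("min_contact_ms", "max_gap_ms", "onset_window_ms"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.onset_window_ms <= 0:
            raise ValidationError("onset_window_ms must be > 0")
        if self.symmetry_mode not in ("integral", "contact_time"):
            raise ValidationError("symmetry_mode must be 'integral' or 'contact_time'")
        if self.speed_delta not in ("relative", "difference"):
            raise ValidationError("speed_delta must be 'relative' or 'difference'")
        if self.pct_delta not in ("difference", "relative"):
            raise ValidationError("pct_delta must be 'difference' or 'relative'")
        if self.range_epsilon < 0:
            raise ValidationError("range_epsilon must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path
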