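# Methods

## Signal model and detection procedure

The input is a per-foot matrix of eight FSR channels sampled at 100 Hz with
8-bit resolution (raw counts 0–255). Sample *i* occurs at *i*·10 ms; times are
derived from indices, never stored per row, which keeps the on-disk CSV free of
rounding drift. An affine calibration (default identity) maps raw counts to
kg/cm²; it is applied lazily at feature extraction, so recordings round-trip
bit-exactly as integers.

**Contact detection.** A foot is in ground contact at sample *i* iff the
maximum over its non-excluded sensors is at or above the contact threshold.
Maximal runs of contact are post-processed in two steps, in this order: gaps
shorter than `max_gap_ms` between consecutive runs are merged (mid-stance
dropouts must not split a stance), then runs shorter than `min_contact_ms` are
discarded (FSR bounce is not a step). Each survivor becomes a step object with
its 8-channel sub-matrix. Contacts truncated by the recording boundary are kept
if long enough, and flagged, rather than silently dropped.

**Per-step features.** Heel strike = first contact sample; toe off = last;
the event's "sensor location" is the above-threshold sensor with maximal value
at that sample, ties broken by lowest sensor id for determinism. Contact time
is the step extent. Average pressure is the mean calibrated value over *all*
non-excluded sensors and all contact samples — the denominator is the whole
foot, not just active sensors, so a lightly loaded foot genuinely averages
lower. A step is **heel-initiated** iff some heel-region sensor exceeds the
contact threshold within the first `onset_window_ms` of contact. The underlying
field usage only counts "heel strikes" without printing a rule; initiation
within a short onset window is the simplest rule consistent with "time and
sensor location when the foot strikes the ground" plus region labels, and it is
what drop-foot (forefoot-initiated contact) violates. Whether heel-region
*participation* later in stance should also count is a genuinely open choice;
we document initiation as ours and expose the window.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `threshold` | 15 | raw counts | ≈6% of full scale: above FSR idle noise, far below stance loading |
| `min_contact_ms` | 150 | ms | stance exceeds 150 ms even at fast cadence; shorter runs are bounce |
| `max_gap_ms` | 60 | ms | mid-stance dropouts are brief; true swing is ≥ hundreds of ms |
| `onset_window_ms` | 50 | ms | initial-contact phase; a heel strike activates the heel immediately |
| `range_epsilon` | 3 | raw counts | a sensor flatter than this over a whole stepping session is dead |
| `symmetry_mode` | `integral` | — | loading share; `contact_time` offered as alternative |
| `speed_delta` / `pct_delta` | `relative` / `difference` | — | see half-split conventions |

None of these is dictated by the hardware; all live in the pipeline config and
are echoed in `--help`.

## Session metrics

**Faulty sensors.** Three modes: `stuck_max` (constant 255 for the whole
recording), `stuck_zero` (constant 0 in every contact episode while another
sensor is active in each), `flatline` (whole-recording range < `range_epsilon`
on a foot that is stepping). Saturated sensors are excluded before the
fault-detection stepping pass, since a stuck-high channel makes the contact
mask all-true. A foot with no detected steps is *unjudgeable*: its silent
sensors are left unflagged rather than declared faulty.

**Symmetry with paired exclusion.** Symmetry is the affected foot's share of
the total pressure-time integral; every faulty sensor id is removed from
*both* feet (the matching process with the opposite foot). Step counting and
heel-strike classification exclude only a foot's own faulty sensors — the
healthy foot should not lose a working heel sensor because its counterpart
died — but the symmetry calculation runs its own detection pass with the
paired exclusion applied to both feet's contact masks, so both feet are judged
through identical sensor subsets end to end. This makes mirrored two-foot data
score exactly 50% with or without any single injected fault, which is the
correctness property the matching process exists for. The study never printed
its symmetry formula; a share-of-total construction is forced by the stated
50% goal, and the pressure-time integral is our default reading (contact-time
share is config-selectable).

**Speed** counts both feet's steps per minute of recording (the reported
steps/minute axis describes the whole walk; doubling one foot's count is the
rejected alternative). Metrics undefined for a session — heel-strike % of a
foot with zero steps, symmetry with zero loading on both feet — propagate as
explicit nulls, never zeros, so downstream means are computed over the
sessions that actually measured the quantity.

## Half-split cohort analysis

Sessions are ordered by date and split into a first (baseline) and second
half; odd counts put the extra session in the first half (ceil/floor — only
the even case is externally fixed). Per metric, the halves' means are
contrasted into a relative score: percentage-point difference for metrics
already on a percent scale (heel-strike %, balance), relative percent change
for speed. Published entries like "+23.8%" for a steps/min metric read most
naturally as relative change, while percent-scale metrics subtract naturally;
both conventions are config-selectable since the source convention is not
printed. Cohort means are simple arithmetic means of per-participant scores,
reported to one decimal; "improving" counts participants with strictly
positive score. The packaged performance table is consumed as printed
(one-decimal deltas), matching what was averaged originally; pipeline outputs
use full precision. Compliance/intensity trends: per half, frequency =
session count / elapsed calendar days (inclusive, ≥1 — calendar-gap handling
is our choice; the source is silent), intensity = mean walk duration.

No inferential statistics are computed: the upstream analysis reports none
(no tests, CIs, or p-values), and n=5 would not support them.

## Synthetic gait generator

The simulator emulates the study conditions, not biomechanics: alternating
stance episodes at a set cadence (each foot cycles at cadence/2 per minute,
phase-offset by half a cycle, so double support appears whenever the stance
fraction exceeds ½); within a stance each sensor follows a half-sine bump over
a region-specific sub-window (heel: first 60%, midfoot/metatarsal: middle 80%,
toe: last 60%), reproducing the overlapping heel-to-toe traces of real foot
strikes qualitatively. Per step, a Bernoulli draw with the foot's heel-strike
probability decides success; failure zeroes that step's heel sensors —
the observable consequence of drop-foot. Loading asymmetry is imposed exactly:
after noise-free envelopes are built, per-foot amplitudes are scaled so the
affected foot carries precisely the requested share of the total pressure-time
integral, anchored so the heavier foot peaks at `peak_pressure` (default 180
counts; absolute amplitude is arbitrary by design since no raw magnitudes are
published). Gaussian noise (default sd 2 counts, typical FSR idle jitter) and
stuck-sensor faults are applied afterwards, then values are rounded and
clipped to [0, 255]. Same seed + same profile ⇒ bit-identical output.
Longitudinal scenarios interpolate every numeric profile parameter linearly
across sessions with session-indexed seeds.

What the simulator does **not** model: realistic kinetics and foot geometry,
stride-time variability, partial/intermittent sensor faults, drift, gait
initiation/termination transients, turning. Tests passing on synthetic data
therefore demonstrate the pipeline's correctness against its own definitions
and its statistical recovery of generating parameters — not clinical validity
on real insole data.

## Numerical choices and degenerate inputs

* Default 60 s sessions at 100 Hz (6,000 × 16 int matrices); the synthetic
  acceptance cohort uses 5 participants × 20 sessions × 30 s, which keeps the
  full end-to-end analysis under a few seconds.
* Gap merge uses strict `<` (a gap exactly `max_gap_ms` long separates steps);
  run filter uses `≥ min_contact_ms` (a run exactly at the minimum survives).
* Onset/feature tie-breaks always resolve to the lowest sensor id.
* Empty recordings: zero samples ⇒ zero duration, no steps; session metrics
  refuse zero-duration input; a trend needs ≥2 sessions; simulation shorter
  than one full stance is a degenerate-input error rather than an empty
  recording, so silent misconfiguration cannot masquerade as "no walking".
* Relative speed change is undefined when the baseline mean is 0 (error, not 0).

## Known limitations

* The heel-initiation rule, detection constants, symmetry formula, speed
  convention, and odd-split rule are this package's documented choices where
  the field source is silent; all are config-exposed.
* Faulty-sensor detection targets hard faults (stuck/saturated/flat);
  intermittent or drifting sensors pass undetected.
* Step-count monotonicity in the contact threshold holds for well-separated
  unimodal bursts (and is tested there); signals with multi-modal stances can
  split at high thresholds once gap-merging disengages.
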