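"""Canonical in-memory data model for photometry sessions, event schedules,
trajectories, and retrograde-tracing cell tables.

All times are seconds from session start; all arrays are numpy float64;
sample positions are 0-based indices on the session's uniform timebase.
Every container validates its own invariants on construction, so readers
and simulators can rely on a single set of checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Event kinds
CS_PLUS = "CS_PLUS"
CS_MINUS = "CS_MINUS"
US = "US"
LASER = "LASER"
EVENT_KINDS = (CS_PLUS, CS_MINUS, US, LASER)

# Cell projection labels
CELL_LABELS = ("dmPFC", "vmPFC", "Both")

# Trial phases for blocked summaries
PHASE_CS_MINUS = "CS_MINUS"
PHASE_CS_PLUS_E = "CS_PLUS_E"
PHASE_CS_PLUS_L = "CS_PLUS_L"
PHASE_CS_PLUS_ALL = "CS_PLUS_ALL"

# Quantification windows, seconds relative to CS onset (20-s CS assumed)
WINDOWS = {
    "onset10": (0.0, 10.0),
    "late10": (10.0, 20.0),
    "offset5": (20.0, 25.0),
}


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class Event:
    """A single timed, typed behavioral event."""

    onset_s: float
    offset_s: float
    kind: str
    trial_index: int

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not self.onset_s < self.offset_s:
            raise ValidationError(
                f"event {self.kind} trial {self.trial_index}: onset must precede offset"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventSchedule:
    """Sorted, validated list of CS/US/laser events defining one session."""

    events: list[Event]

    def __post_init__(self):
        if not self.events:
            raise ValidationError("no events")
        self.events = sorted(self.events, key=lambda e: (e.onset_s, e.offset_s))

    def of_kind(self, *kinds: str) -> list[Event]:
        return [e for e in self.events if e.kind in kinds]

    def cs_events(self) -> list[Event]:
        return self.of_kind(CS_PLUS, CS_MINUS)

    @property
    def duration_s(self) -> float:
        return max(e.offset_s for e in self.events)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.kind] = out.get(e.kind, 0) + 1
        return out


@dataclass
class PhotometrySession:
    """Raw two-channel fluorescence for one recording site.

    ``f_signal`` is the calcium-dependent channel (~470 nm excitation),
    ``f_control`` the isosbestic channel (~410-415 nm), both sampled on a
    shared uniform timebase at ``rate_hz``.
    """

    time_s: np.ndarray
    f_signal: np.ndarray
    f_control: np.ndarray
    rate_hz: float
    site_id: str = "RE"
    subject_id: str = "subject"

    def __post_init__(self):
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.f_signal = _as_float_array(self.f_signal, "f_signal")
        self.f_control = _as_float_array(self.f_control, "f_control")
        n = len(self.time_s)
        if len(self.f_signal) != n or len(self.f_control) != n:
            raise ValidationError(
                "channel length mismatch: time_s has "
                f"{n} samples, signal {len(self.f_signal)}, control {len(self.f_control)}"
            )
        if n < 2:
            raise ValidationError("session needs at least 2 samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time_s must be strictly increasing")
        for name, arr in (("f_signal", self.f_signal), ("f_control", self.f_control)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValidationError(f"{name} is not finite at row {bad[0]}")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class CorrectedTrace:
    """Motion-corrected fluorescence: signal minus the fitted isosbestic term."""

    time_s: np.ndarray
    value: np.ndarray
    fit_slope: float
    fit_intercept: float
    rate_hz: float

    def __post_init__(self):
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.value = _as_float_array(self.value, "value")
        if len(self.time_s) != len(self.value):
            raise ValidationError("time_s and value must have equal length")
        if not (np.isfinite(self.fit_slope) and np.isfinite(self.fit_intercept)):
            raise ValidationError("fit coefficients must be finite")


@dataclass
class TrialMatrix:
    """Event-aligned trial x time array with per-trial labels.

    ``z`` holds one row per CS trial on a uniform relative timebase
    ``rel_time_s`` spanning [-pre, +post] seconds around CS onset. Rows are
    baseline z-scores unless the matrix was built with normalization off
    (``normalized`` False), in which case rows are raw corrected fluorescence.
    """

    z: np.ndarray
    rel_time_s: np.ndarray
    kinds: list[str]
    trial_indices: list[int]
    subject_id: str = "subject"
    site_id: str = "RE"
    session: str = "session"
    baseline_window_s: tuple[float, float] = (-20.0, 0.0)
    normalized: bool = True

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rel_time_s = _as_float_array(self.rel_time_s, "rel_time_s")
        if self.z.ndim != 2:
            raise ValidationError("z must be trials x samples")
        if self.z.shape[1] != len(self.rel_time_s):
            raise ValidationError("z columns must match rel_time_s length")
        if self.z.shape[0] != len(self.kinds) or self.z.shape[0] != len(self.trial_indices):
            raise ValidationError("per-trial labels must match number of rows")
        dt = np.diff(self.rel_time_s)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError("rel_time_s must be uniform")

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class AUCRecord:
    """One trial x window scalar summary of the aligned z-scored trace.

    ``value`` is the trapezoidal time-integral over the window (z*s);
    ``mean_z`` is the corresponding time-average (z). The two are linked by
    value = mean_z * window length on a uniform grid.
    """

    subject_id: str
    site_id: str
    session: str
    kind: str
    trial_index: int
    window: str
    value: float
    mean_z: float
    phase: str = "per-trial"


@dataclass
class Trajectory:
    """Tracked position time series (e.g. pose-estimation centroid export)."""

    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate_hz: float

    def __post_init__(self):
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        if not (len(self.time_s) == len(self.x) == len(self.y)):
            raise ValidationError("trajectory columns must have equal length")
        for name, arr in (("x", self.x), ("y", self.y)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValidationError(f"{name} is not finite at row {bad[0]}")
        if not self.frame_rate_hz > 0:
            raise ValidationError("frame_rate_hz must be positive")


@dataclass(frozen=True)
class CellRecord:
    """One retrogradely labeled neuron: region, coordinates, projection label.

    ``ap_mm`` is the anterior-posterior position in mm from bregma; ``ml_um``
    the absolute distance from the midline in micrometres.
    """

    region: str
    ap_mm: float
    ml_um: float
    label: str

    def __post_init__(self):
        if self.label not in CELL_LABELS:
            raise ValidationError(f"unknown projection label {self.label!r}")
        if self.ml_um < 0:
            raise ValidationError("ml_um must be non-negative")
        if not (np.isfinite(self.ap_mm) and np.isfinite(self.ml_um)):
            raise ValidationError("cell coordinates must be finite")


@dataclass(frozen=True)
class ResponseProfile:
    """Programmed event-evoked transients for the session simulator.

    Amplitudes are peak values in raw fluorescence units; with the default
    noise model (unit white-noise SD) they read directly as peak z-scores.
    ``learning_curve`` scales the CS+ onset transient per CS+ trial (values in
    [0, 1]); the post-offset suppression amplitude is applied unscaled, giving
    the biphasic (onset excitation, offset suppression) extinction response.
    """

    cs_plus_onset_amp: float = 1.5
    cs_minus_amp: float = 0.0
    us_amp: float = 3.0
    offset_suppression_amp: float = -1.0
    transient_rise_s: float = 0.5
    transient_decay_s: float = 3.0
    learning_curve: tuple[float, ...] = ()

    def __post_init__(self):
        if not 0 < self.transient_rise_s < self.transient_decay_s:
            raise ValidationError("require 0 < rise < decay")
        if any(not 0 <= c <= 1 for c in self.learning_curve):
            raise ValidationError("learning_curve values must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Artifact model for the forward simulator.

    The shared motion process enters both channels with gains proportional to
    their baselines by default (a multiplicative artifact), which is the
    structure single-regressor isosbestic correction removes. Bleaching is an
    exponential approach to (1 - bleach_frac) of baseline with time constant
    ``bleach_tau_s``, identical in shape for the two channels.
    """

    bleach_tau_s: float = 600.0
    bleach_frac: float = 0.2
    motion_sd: float = 3.0
    motion_gain_signal: float = 1.0
    motion_gain_control: float = 0.5
    white_sd: float = 1.0
    baseline_signal: float = 100.0
    baseline_control: float = 50.0

    def __post_init__(self):
        if self.bleach_tau_s <= 0:
            raise ValidationError("bleach_tau_s must be positive")
        if not 0 <= self.bleach_frac < 1:
            raise ValidationError("bleach_frac must lie in [0, 1)")
        if self.motion_sd < 0 or self.white_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        if self.baseline_signal <= 0 or self.baseline_control <= 0:
            raise ValidationError("baselines must be positive")


@dataclass(frozen=True)
class FreezingResult:
    """Detected immobility epochs and per-CS freezing percentages."""

    epochs: tuple[tuple[float, float], ...]
    percent_by_event: tuple[float, ...]
    threshold_px_per_s: float
    min_duration_s: float

    def __post_init__(self):
        prev_end = -np.inf
        for start, end in self.epochs:
            if start >= end:
                raise ValidationError("epoch start must precede end")
            if start < prev_end:
                raise ValidationError("epochs must be sorted and non-overlapping")
            prev_end = end
        for p in self.percent_by_event:
            if not 0 <= p <= 100:
                raise ValidationError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class StatResult:
    """One statistical test outcome.

    ``df`` is the (possibly fractional, sphericity-corrected) degrees of
    freedom actually used for the p-value; ``df_uncorrected`` the integer
    design df; ``epsilon`` the Greenhouse-Geisser factor when a correction
    applies. ``posthoc`` holds {contrast, statistic, p_adj} dicts.
    """

    test: str
    statistic: float
    p: float
    df: tuple[float, ...] | None = None
    df_uncorrected: tuple[int, ...] | None = None
    epsilon: float | None = None
    posthoc: list[dict] | None = None
    note: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValidationError("p must lie in [0, 1]")
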