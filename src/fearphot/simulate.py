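"""Synthetic session generator: event schedules, two-channel photometry,
tracked trajectories, and retrograde-labeling cell maps.

The generator is the ground truth for the rest of the pipeline: every
downstream stage is validated by planting known structure here and checking
it is recovered. Session schedules follow the four-day differential
conditioning design (habituation, conditioning, extinction, retrieval, plus
optogenetic variants); the fluorescence forward model is

    signal(t)  = B_s * bleach(t) + transients(t) + g_s * M(t) + white noise
    control(t) = B_c * bleach(t)               + g_c * M(t) + white noise

with one shared slow motion process M(t) and a peak-normalized
difference-of-exponentials transient kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .core import (
    CS_MINUS,
    CS_PLUS,
    LASER,
    US,
    CellRecord,
    Event,
    EventSchedule,
    NoiseModel,
    PhotometrySession,
    ResponseProfile,
    Trajectory,
    ValidationError,
)

DAYS = (
    "habituation",
    "conditioning",
    "extinction",
    "retrieval",
    "opto_extinction",
    "opto_retrieval",
)


@dataclass(frozen=True)
class ScheduleParams:
    """Session layout knobs.

    ITIs (onset-to-onset gaps minus the CS duration) are drawn uniformly on
    [iti_mean - iti_jitter, iti_mean + iti_jitter]; the mean comes from the
    day type. ``lead_in_s`` seconds precede the first CS so a 20-s baseline
    always exists.
    """

    cs_duration_s: float = 20.0
    us_duration_s: float = 2.0
    iti_jitter_s: float = 20.0
    lead_in_s: float = 60.0
    laser_pre_s: float = 0.4
    laser_post_s: float = 3.0

    def __post_init__(self):
        if self.cs_duration_s <= 0 or self.us_duration_s <= 0:
            raise ValidationError("durations must be positive")
        if self.iti_jitter_s < 0:
            raise ValidationError("iti_jitter_s must be non-negative")


# (n CS-, n CS+, pair US with CS+, ITI mean s) per day type
_DAY_LAYOUT = {
    "habituation": (30, 0, False, 30.0),
    "conditioning": (5, 5, True, 90.0),
    "extinction": (5, 30, False, 70.0),
    "retrieval": (5, 10, False, 70.0),
    "opto_extinction": (0, 30, False, 70.0),
    "opto_retrieval": (0, 6, False, 70.0),
}


def _max_run(order: list[str], kind: str | None = None) -> int:
    best = run = 0
    prev = None
    for k in order:
        run = run + 1 if k == prev else 1
        prev = k
        if kind is None or k == kind:
            best = max(best, run)
    return best


def _interleave(n_minus: int, n_plus: int, rng: np.random.Generator) -> list[str]:
    """Pseudorandom CS order with at most 2 consecutive same-type trials.

    When one type heavily outnumbers the other (e.g. 5 CS- among 30 CS+ in
    extinction) the two-in-a-row cap is combinatorially impossible for the
    majority type, so it is applied to the minority type only.
    """
    kinds = [CS_MINUS] * n_minus + [CS_PLUS] * n_plus
    if n_minus == 0 or n_plus == 0:
        return kinds
    lo, hi = min(n_minus, n_plus), max(n_minus, n_plus)
    both_feasible = hi <= 2 * (lo + 1)
    minority = CS_MINUS if n_minus <= n_plus else CS_PLUS
    for _ in range(2000):
        order = [str(k) for k in rng.permutation(kinds)]
        if (_max_run(order) if both_feasible else _max_run(order, minority)) <= 2:
            return order
    raise ValidationError("could not interleave trials without long runs")


def make_schedule(
    day: str,
    params: ScheduleParams | None = None,
    seed: int = 0,
    laser_mode: str | None = None,
) -> EventSchedule:
    """Build the event schedule for one session day.

    Day layouts: habituation 30 CS- (ITI mean 30 s); conditioning 5 CS- and
    5 CS+ each followed immediately by a 2-s US (ITI mean 90 s); extinction
    5 CS- + 30 CS+ (ITI mean 70 s); retrieval 5 CS- + 10 CS+ (ITI mean 70 s).
    Optogenetic days carry CS+ only; ``laser_mode`` "inhibition" adds one
    laser epoch per CS from 400 ms before onset to 3 s after offset,
    "activation" adds a 10 Hz pulse train spanning the CS.
    """
    if day not in DAYS:
        raise ValidationError(f"unknown day {day!r}; expected one of {DAYS}")
    if laser_mode not in (None, "inhibition", "activation"):
        raise ValidationError(f"unknown laser_mode {laser_mode!r}")
    params = params or ScheduleParams()
    n_minus, n_plus, pair_us, iti_mean = _DAY_LAYOUT[day]
    rng = np.random.default_rng(seed)
    order = _interleave(n_minus, n_plus, rng)

    events: list[Event] = []
    t = params.lead_in_s
    counters = {CS_PLUS: 0, CS_MINUS: 0}
    lo = max(iti_mean - params.iti_jitter_s, 1.0)
    hi = iti_mean + params.iti_jitter_s
    for i, kind in enumerate(order):
        onset, offset = t, t + params.cs_duration_s
        idx = counters[kind]
        counters[kind] += 1
        events.append(Event(onset, offset, kind, idx))
        if pair_us and kind == CS_PLUS:
            # US onset exactly at CS+ offset
            events.append(Event(offset, offset + params.us_duration_s, US, idx))
        if day.startswith("opto") and laser_mode == "inhibition":
            events.append(
                Event(onset - params.laser_pre_s, offset + params.laser_post_s, LASER, i)
            )
        elif day.startswith("opto") and laser_mode == "activation":
            events.append(Event(onset, offset, LASER, i))
        t = offset + rng.uniform(lo, hi)
    return EventSchedule(events)


def transient_kernel(
    t: np.ndarray, rise_s: float, decay_s: float
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel, zero for t < 0."""
    if not 0 < rise_s < decay_s:
        raise ValidationError("require 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s) - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    # peak at t* = ln(d/r) / (1/r - 1/d)
    t_peak = math.log(decay_s / rise_s) / (1 / rise_s - 1 / decay_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    return out / peak


def kernel_integral(rise_s: float, decay_s: float, upto_s: float | None = None) -> float:
    """Closed-form time-integral of the peak-normalized kernel on [0, upto]."""
    t_peak = math.log(decay_s / rise_s) / (1 / rise_s - 1 / decay_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    if upto_s is None:
        raw = decay_s - rise_s
    else:
        raw = decay_s * (1 - math.exp(-upto_s / decay_s)) - rise_s * (
            1 - math.exp(-upto_s / rise_s)
        )
    return raw / peak


def _motion_process(n: int, rate_hz: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Shared slow artifact: Gaussian random walk low-passed at 0.5 Hz,
    standardized to zero mean and the requested SD."""
    if sd == 0 or n < 10:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    cutoff = 0.5 / (rate_hz / 2)
    if cutoff < 1:
        b, a = butter(2, cutoff)
        walk = filtfilt(b, a, walk)
    walk = walk - walk.mean()
    s = walk.std()
    return walk * (sd / s) if s > 0 else walk


def simulate_session(
    schedule: EventSchedule,
    profile: ResponseProfile,
    noise: NoiseModel,
    rate_hz: float = 10.0,
    seed: int = 0,
    tail_s: float = 60.0,
    site_id: str = "RE",
    subject_id: str = "subject",
) -> PhotometrySession:
    """Simulate one two-channel photometry session on a uniform timebase.

    Transients: CS+ onset kernels scaled per-trial by ``profile.learning_curve``
    (all ones if empty), a fixed post-offset suppression kernel on every CS+,
    CS- onset kernels, and US-onset kernels. The motion process is shared
    between channels; white noise is independent per channel.
    """
    if rate_hz <= 0:
        raise ValidationError("rate_hz must be positive")
    n_plus = len(schedule.of_kind(CS_PLUS))
    curve = np.asarray(profile.learning_curve, dtype=float)
    if curve.size == 0:
        curve = np.ones(max(n_plus, 1))
    elif curve.size != n_plus and n_plus > 0:
        raise ValidationError(
            f"learning_curve length {curve.size} != {n_plus} CS+ trials in schedule"
        )

    duration = schedule.duration_s + tail_s
    n = int(round(duration * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)

    transients = np.zeros(n)

    def add_kernel(t0: float, amp: float):
        if amp == 0:
            return
        i0 = int(np.ceil(t0 * rate_hz))
        if i0 >= n:
            return
        rel = t[i0:] - t0
        transients[i0:] += amp * transient_kernel(
            rel, profile.transient_rise_s, profile.transient_decay_s
        )

    for ev in schedule.events:
        if ev.kind == CS_PLUS:
            add_kernel(ev.onset_s, profile.cs_plus_onset_amp * curve[ev.trial_index])
            add_kernel(ev.offset_s, profile.offset_suppression_amp)
        elif ev.kind == CS_MINUS:
            add_kernel(ev.onset_s, profile.cs_minus_amp)
        elif ev.kind == US:
            add_kernel(ev.onset_s, profile.us_amp)

    bleach = 1.0 - noise.bleach_frac * (1.0 - np.exp(-t / noise.bleach_tau_s))
    motion = _motion_process(n, rate_hz, noise.motion_sd, rng)
    f_signal = (
        noise.baseline_signal * bleach
        + transients
        + noise.motion_gain_signal * motion
        + noise.white_sd * rng.standard_normal(n)
    )
    f_control = (
        noise.baseline_control * bleach
        + noise.motion_gain_control * motion
        + noise.white_sd * rng.standard_normal(n)
    )
    return PhotometrySession(
        time_s=t,
        f_signal=f_signal,
        f_control=f_control,
        rate_hz=rate_hz,
        site_id=site_id,
        subject_id=subject_id,
    )


def extinction_learning_curve(n_trials: int, decay_trials: float = 5.0) -> tuple[float, ...]:
    """Exponentially decaying per-trial scaling: prominent on the first
    trials, approaching zero by late extinction."""
    k = np.arange(n_trials)
    return tuple(np.exp(-k / decay_trials))


def simulate_trajectory(
    freeze_epochs: list[tuple[float, float]],
    duration_s: float,
    frame_rate_hz: float = 30.0,
    move_speed: float = 2.0,
    jitter: float = 0.05,
    seed: int = 0,
) -> Trajectory:
    """Random-walk position trace with planted immobility epochs.

    Per-frame displacement has scale ``move_speed`` px outside freeze epochs
    and ``jitter`` px inside (respiration-scale residual motion).
    """
    if frame_rate_hz <= 0 or duration_s <= 0:
        raise ValidationError("rates and duration must be positive")
    if move_speed < 0 or jitter < 0:
        raise ValidationError("step scales must be non-negative")
    epochs = sorted(freeze_epochs)
    prev_end = 0.0
    for start, end in epochs:
        if start >= end:
            raise ValidationError("epoch start must precede end")
        if start < prev_end:
            raise ValidationError("overlapping freeze epochs")
        if start < 0 or end > duration_s:
            raise ValidationError("epochs must lie within [0, duration]")
        prev_end = end

    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    frozen = np.zeros(n, dtype=bool)
    for start, end in epochs:
        frozen[(t >= start) & (t < end)] = True
    rng = np.random.default_rng(seed)
    scale = np.where(frozen, jitter, move_speed)
    steps = rng.standard_normal((2, n)) * scale
    steps[:, 0] = 0.0
    pos = np.cumsum(steps, axis=1)
    return Trajectory(time_s=t, x=pos[0] + 100.0, y=pos[1] + 100.0, frame_rate_hz=frame_rate_hz)


def simulate_cellmap(
    n_per_label: dict[str, int],
    centers: dict[str, tuple[float, float]],
    spreads: dict[str, tuple[float, float]],
    both_fraction: float = 0.0,
    region: str = "RE",
    seed: int = 0,
) -> list[CellRecord]:
    """Gaussian projection-labeled cell clusters for one thalamic region.

    For each label, ``n_per_label[label]`` cells are drawn from a Gaussian at
    ``centers[label] = (ap_mm, ml_um)`` with per-axis SDs ``spreads[label]``.
    Each dmPFC/vmPFC cell is independently relabeled "Both" (a double-labeled
    neuron, keeping its position) with probability ``both_fraction``.
    """
    if not 0 <= both_fraction <= 1:
        raise ValidationError("both_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []
    for label, n in n_per_label.items():
        ap0, ml0 = centers[label]
        ap_sd, ml_sd = spreads[label]
        if ap_sd <= 0 or ml_sd <= 0:
            raise ValidationError("spreads must be positive")
        ap = rng.normal(ap0, ap_sd, n)
        ml = np.abs(rng.normal(ml0, ml_sd, n))
        dual = rng.random(n) < both_fraction if label in ("dmPFC", "vmPFC") else np.zeros(n, bool)
        for a, m, d in zip(ap, ml, dual):
            cells.append(CellRecord(region=region, ap_mm=float(a), ml_um=float(m),
                                    label="Both" if d else label))
    return cells


def null_profile() -> ResponseProfile:
    """Profile with every planted amplitude zero (no evoked structure)."""
    return ResponseProfile(
        cs_plus_onset_amp=0.0, cs_minus_amp=0.0, us_amp=0.0, offset_suppression_amp=0.0
    )


def biphasic_extinction_profile(
    n_cs_plus: int = 30,
    onset_amp: float = 1.5,
    offset_amp: float = -1.0,
) -> ResponseProfile:
    """The extinction-phase response of vmPFC-projecting midline thalamic
    neurons: onset excitation prominent on early trials and decaying to zero,
    plus a constant post-offset suppression."""
    return ResponseProfile(
        cs_plus_onset_amp=onset_amp,
        offset_suppression_amp=offset_amp,
        cs_minus_amp=0.0,
        us_amp=0.0,
        learning_curve=extinction_learning_curve(n_cs_plus),
    )
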