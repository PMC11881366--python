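"""Freezing quantification from tracked-position trajectories.

Freezing is scored with the field-standard immobility rule: the smoothed
per-frame motion energy (displacement magnitude times frame rate, px/s)
must stay below a threshold for at least a minimum bout duration. Each CS
then receives the percentage of its 20-s period spent inside a freezing
epoch; the pre-CS baseline uses the 20 s before the first CS-.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CS_MINUS,
    CS_PLUS,
    EventSchedule,
    FreezingResult,
    Trajectory,
    ValidationError,
)


def motion_energy(traj: Trajectory, smooth_s: float = 0.1) -> np.ndarray:
    """Per-frame speed estimate in px/s, boxcar-smoothed over ``smooth_s``.

    The first frame repeats the second so the output has one value per frame.
    """
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    speed = np.hypot(dx, dy) * traj.frame_rate_hz
    speed = np.concatenate([speed[:1], speed])
    w = max(1, int(round(smooth_s * traj.frame_rate_hz)))
    if w > 1:
        kernel = np.ones(w) / w
        # reflect-pad so edges keep local scale
        padded = np.concatenate([speed[w - 1:0:-1], speed, speed[-2:-w - 1:-1]])
        speed = np.convolve(padded, kernel, mode="same")[w - 1 : w - 1 + len(traj.x)]
    return speed


def detect_freezing(
    energy: np.ndarray,
    frame_rate_hz: float,
    threshold: float = 15.0,
    min_duration_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Maximal sub-threshold runs lasting at least ``min_duration_s``.

    Returns epochs as (start_s, end_s) on the frame clock.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if frame_rate_hz <= 0:
        raise ValidationError("frame_rate_hz must be positive")
    below = np.asarray(energy) < threshold
    epochs: list[tuple[float, float]] = []
    n = len(below)
    i = 0
    min_frames = int(np.ceil(min_duration_s * frame_rate_hz))
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 >= min_frames:
                epochs.append((i / frame_rate_hz, (j + 1) / frame_rate_hz))
            i = j + 1
        else:
            i += 1
    return epochs


def _overlap_s(epochs: list[tuple[float, float]], lo: float, hi: float) -> float:
    return sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in epochs)


def percent_freezing(
    epochs: list[tuple[float, float]],
    schedule: EventSchedule,
    kinds: tuple[str, ...] = (CS_PLUS, CS_MINUS),
    baseline_s: float = 20.0,
) -> tuple[dict, list[dict]]:
    """Per-CS freezing percentages plus the pre-session baseline.

    Returns ``(baseline, rows)`` where ``baseline`` is a dict with the
    percentage over the ``baseline_s`` seconds before the first CS- (first
    CS if no CS- exists) and ``rows`` holds one dict per CS event:
    {kind, trial_index, onset_s, percent}.
    """
    cs = [e for e in schedule.events if e.kind in kinds]
    if not cs:
        raise ValidationError("schedule has no CS events of the requested kinds")
    minus = [e for e in cs if e.kind == CS_MINUS]
    anchor = (minus or cs)[0]
    b_lo = max(0.0, anchor.onset_s - baseline_s)
    base = {
        "window_s": (b_lo, anchor.onset_s),
        "percent": 100.0 * _overlap_s(epochs, b_lo, anchor.onset_s)
        / max(anchor.onset_s - b_lo, 1e-12),
    }
    rows = [
        {
            "kind": e.kind,
            "trial_index": e.trial_index,
            "onset_s": e.onset_s,
            "percent": 100.0 * _overlap_s(epochs, e.onset_s, e.offset_s) / e.duration_s,
        }
        for e in cs
    ]
    return base, rows


def score_freezing(
    traj: Trajectory,
    schedule: EventSchedule,
    threshold: float = 15.0,
    min_duration_s: float = 1.0,
    smooth_s: float = 0.1,
) -> FreezingResult:
    """End-to-end freezing quantification for one session."""
    energy = motion_energy(traj, smooth_s=smooth_s)
    epochs = detect_freezing(energy, traj.frame_rate_hz, threshold, min_duration_s)
    _, rows = percent_freezing(epochs, schedule)
    return FreezingResult(
        epochs=tuple(epochs),
        percent_by_event=tuple(r["percent"] for r in rows),
        threshold_px_per_s=threshold,
        min_duration_s=min_duration_s,
    )
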