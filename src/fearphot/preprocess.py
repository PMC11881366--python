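"""Isosbestic motion correction and baseline z-scoring of CS-aligned trials.

The calcium-dependent channel is corrected by subtracting a session-wide
ordinary-least-squares fit of the isosbestic control channel:

    corrected(t) = F470(t) - (slope * Fiso(t) + intercept)

Any artifact shared by the two channels (motion, and photobleaching when it
enters both channels proportionally) is removed; calcium transients, absent
from the isosbestic channel, survive. Each CS trial is then z-scored against
the mean and SD of the 20 s immediately preceding its onset, making all
downstream quantification invariant to the raw fluorescence scale.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CS_MINUS,
    CS_PLUS,
    CorrectedTrace,
    EventSchedule,
    PhotometrySession,
    TrialMatrix,
    ValidationError,
)


def fit_control(f_signal: np.ndarray, f_control: np.ndarray) -> tuple[float, float]:
    """OLS fit of the signal channel on the control channel.

    Returns ``(slope, intercept)`` minimizing
    sum((signal - slope*control - intercept)^2).
    """
    s = np.asarray(f_signal, dtype=float)
    c = np.asarray(f_control, dtype=float)
    if s.shape != c.shape or s.ndim != 1:
        raise ValidationError("channels must be 1-D and equal length")
    if len(s) < 2:
        raise ValidationError("need at least 2 samples")
    c_var = np.var(c)
    if c_var == 0:
        raise ValidationError("degenerate control channel (zero variance)")
    slope = float(np.cov(s, c, bias=True)[0, 1] / c_var)
    intercept = float(s.mean() - slope * c.mean())
    return slope, intercept


def motion_correct(session: PhotometrySession) -> CorrectedTrace:
    """Subtract the fitted isosbestic term from the signal channel.

    By the OLS normal equations the corrected trace has exactly zero mean
    and its variance never exceeds the raw signal variance.
    """
    slope, intercept = fit_control(session.f_signal, session.f_control)
    value = session.f_signal - (slope * session.f_control + intercept)
    return CorrectedTrace(
        time_s=session.time_s,
        value=value,
        fit_slope=slope,
        fit_intercept=intercept,
        rate_hz=session.rate_hz,
    )


def align_trials(
    trace: CorrectedTrace,
    schedule: EventSchedule,
    baseline_s: float = 20.0,
    window_s: tuple[float, float] = (20.0, 45.0),
    normalize: bool = True,
    subject_id: str = "subject",
    site_id: str = "RE",
    session: str = "session",
) -> TrialMatrix:
    """Slice the corrected trace into CS-aligned rows, optionally z-scored.

    Each CS (CS+ or CS-) trial spans [-pre, +post] s around its onset
    (``window_s = (pre, post)``). With ``normalize`` True each row is
    z-scored against the mean and SD of the ``baseline_s`` seconds strictly
    preceding onset, i.e. z(t) = (value(t) - mu_base) / sd_base.
    """
    pre, post = window_s
    if baseline_s <= 0 or pre < 0 or post <= 0:
        raise ValidationError("baseline and window lengths must be positive")
    rate = trace.rate_hz
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    n_base = int(round(baseline_s * rate))
    rel_time = np.arange(-n_pre, n_post + 1) / rate

    rows, kinds, indices = [], [], []
    for ev in schedule.cs_events():
        onset_idx = int(np.searchsorted(trace.time_s, ev.onset_s))
        lo, hi = onset_idx - n_pre, onset_idx + n_post + 1
        base_lo = onset_idx - n_base
        if base_lo < 0 or lo < 0:
            raise ValidationError(
                f"{ev.kind} trial {ev.trial_index}: CS too close to session start "
                f"for a {baseline_s:.0f}-s baseline"
            )
        if hi > len(trace.value):
            raise ValidationError(
                f"{ev.kind} trial {ev.trial_index}: session ends before +{post:.0f} s window"
            )
        seg = trace.value[lo:hi]
        if normalize:
            base = trace.value[base_lo:onset_idx]
            mu, sd = base.mean(), base.std(ddof=0)
            if sd == 0:
                raise ValidationError(
                    f"{ev.kind} trial {ev.trial_index}: zero baseline SD"
                )
            seg = (seg - mu) / sd
        rows.append(seg)
        kinds.append(ev.kind)
        indices.append(ev.trial_index)
    if not rows:
        raise ValidationError("schedule contains no CS events")
    return TrialMatrix(
        z=np.vstack(rows),
        rel_time_s=rel_time,
        kinds=kinds,
        trial_indices=indices,
        subject_id=subject_id,
        site_id=site_id,
        session=session,
        baseline_window_s=(-baseline_s, 0.0),
        normalized=normalize,
    )


def zscore_trials(
    trace: CorrectedTrace,
    schedule: EventSchedule,
    baseline_s: float = 20.0,
    window_s: tuple[float, float] = (20.0, 45.0),
    **kwargs,
) -> TrialMatrix:
    """Baseline z-scored CS-aligned trial matrix (see :func:`align_trials`)."""
    return align_trials(trace, schedule, baseline_s, window_s, normalize=True, **kwargs)


def preprocess_session(
    session: PhotometrySession,
    schedule: EventSchedule,
    baseline_s: float = 20.0,
    window_s: tuple[float, float] = (20.0, 45.0),
    session_name: str = "session",
) -> TrialMatrix:
    """Motion-correct then z-score in one step."""
    trace = motion_correct(session)
    return zscore_trials(
        trace,
        schedule,
        baseline_s=baseline_s,
        window_s=window_s,
        subject_id=session.subject_id,
        site_id=session.site_id,
        session=session_name,
    )
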