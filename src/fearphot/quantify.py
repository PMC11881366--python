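"""Peri-CS window quantification and trial blocking.

Three fixed windows relative to CS onset summarize the biphasic response of
a 20-s CS: ``onset10`` [0, 10] s (onset excitation), ``late10`` [10, 20] s
(late CS period), and ``offset5`` [20, 25] s (post-offset suppression).
Each trial yields both the trapezoidal time-integral (z*s, the AUC) and the
time-average (z) over the window; extinction trials are blocked into early
(first 5 CS+), late (last 5 CS+), and CS- phases for subject-level summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CS_MINUS,
    CS_PLUS,
    PHASE_CS_MINUS,
    PHASE_CS_PLUS_E,
    PHASE_CS_PLUS_L,
    WINDOWS,
    AUCRecord,
    TrialMatrix,
    ValidationError,
)


def _window_bounds(window: str | tuple[float, float]) -> tuple[float, float, str]:
    if isinstance(window, str):
        if window not in WINDOWS:
            raise ValidationError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
        lo, hi = WINDOWS[window]
        return lo, hi, window
    lo, hi = window
    return float(lo), float(hi), f"[{lo},{hi})"


def window_auc(trials: TrialMatrix, window: str | tuple[float, float]) -> list[AUCRecord]:
    """Per-trial trapezoidal AUC and mean z over one peri-onset window.

    The window is closed on both ends on the trial's uniform grid, so the
    integral over [0, 20] equals the sum of the integrals over [0, 10] and
    [10, 20] exactly at shared grid nodes.
    """
    lo, hi, name = _window_bounds(window)
    t = trials.rel_time_s
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValidationError(
            f"window [{lo}, {hi}] exceeds aligned range [{t[0]}, {t[-1]}]"
        )
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValidationError("window contains fewer than 2 samples")
    tw = t[mask]
    length = tw[-1] - tw[0]
    records = []
    for i in range(trials.n_trials):
        value = float(np.trapezoid(trials.z[i, mask], tw))
        records.append(
            AUCRecord(
                subject_id=trials.subject_id,
                site_id=trials.site_id,
                session=trials.session,
                kind=trials.kinds[i],
                trial_index=trials.trial_indices[i],
                window=name,
                value=value,
                mean_z=value / length,
            )
        )
    return records


def block_trials(records: list[AUCRecord], block_size: int = 5) -> list[AUCRecord]:
    """Phase-averaged records: CS- mean, early (first ``block_size``) and
    late (last ``block_size``) CS+ means, per subject x site x session x window.

    Per-trial records should be kept alongside these summaries for
    trial-course analyses; this function only adds the blocked phases.
    """
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValidationError("no records to block")
    out: list[AUCRecord] = []
    keys = ["subject_id", "site_id", "session", "window"]
    for group_key, grp in df.groupby(keys, sort=False):
        plus = grp[grp["kind"] == CS_PLUS].sort_values("trial_index")
        minus = grp[grp["kind"] == CS_MINUS]
        meta = dict(zip(keys, group_key))
        if len(plus) and len(plus) < block_size:
            raise ValidationError(
                f"only {len(plus)} CS+ trials; need at least block_size={block_size}"
            )

        def summary(sub: pd.DataFrame, phase: str, kind: str) -> AUCRecord:
            return AUCRecord(
                subject_id=meta["subject_id"], site_id=meta["site_id"],
                session=meta["session"], kind=kind, trial_index=-1,
                window=meta["window"], value=float(sub["value"].mean()),
                mean_z=float(sub["mean_z"].mean()), phase=phase,
            )

        if len(minus):
            out.append(summary(minus, PHASE_CS_MINUS, CS_MINUS))
        if len(plus):
            out.append(summary(plus.head(block_size), PHASE_CS_PLUS_E, CS_PLUS))
            out.append(summary(plus.tail(block_size), PHASE_CS_PLUS_L, CS_PLUS))
    return out


def records_frame(records: list[AUCRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of AUC records (one row per record)."""
    return pd.DataFrame([r.__dict__ for r in records])


def population_trace(
    trial_matrices: list[TrialMatrix], kind: str | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population mean +/- SEM trace: trials are averaged within subject
    first, then the mean and SEM are taken across subjects.

    Returns ``(rel_time_s, mean, sem)``. With a single subject the SEM is 0.
    """
    if not trial_matrices:
        raise ValidationError("empty group")
    ref = trial_matrices[0].rel_time_s
    per_subject = []
    for tm in trial_matrices:
        if len(tm.rel_time_s) != len(ref) or not np.allclose(tm.rel_time_s, ref):
            raise ValidationError("trial matrices must share a relative timebase")
        rows = (
            np.array([k == kind for k in tm.kinds]) if kind is not None
            else np.ones(tm.n_trials, dtype=bool)
        )
        if not rows.any():
            raise ValidationError(f"subject {tm.subject_id} has no {kind} trials")
        per_subject.append(tm.z[rows].mean(axis=0))
    stack = np.vstack(per_subject)
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ref, mean, sem
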