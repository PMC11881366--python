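"""Readers and writers for the on-disk session store.

Canonical plain-text layouts:

* photometry session — long CSV with columns ``time_s, channel, fluorescence``
  (``channel`` in {signal, control}; rows may be interleaved in acquisition
  order) or an HDF5 container with datasets ``/time_s``, ``/signal``,
  ``/control`` and attrs ``rate_hz``, ``site_id``, ``subject_id``;
* events — CSV ``onset_s, offset_s, kind, trial_index``;
* trajectory — CSV ``time_s, x, y``;
* cells — CSV ``region, ap_mm, ml_um, label``.

Every reader is a total validator: the returned object's invariants are
checked on load and violations raise :class:`~fearphot.core.ValidationError`
naming the offending row where possible.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    CellRecord,
    Event,
    EventSchedule,
    PhotometrySession,
    Trajectory,
    ValidationError,
)

_SESSION_COLS = ["time_s", "channel", "fluorescence"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def write_session(session: PhotometrySession, path: str | Path) -> None:
    """Write a session; ``.h5``/``.hdf5`` suffix selects HDF5, else long CSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("time_s", data=session.time_s)
            f.create_dataset("signal", data=session.f_signal)
            f.create_dataset("control", data=session.f_control)
            f.attrs["rate_hz"] = session.rate_hz
            f.attrs["site_id"] = session.site_id
            f.attrs["subject_id"] = session.subject_id
        return
    # interleave the two channels in time order, as acquisition software does
    df = pd.DataFrame(
        {
            "time_s": np.repeat(session.time_s, 2),
            "channel": ["signal", "control"] * len(session),
            "fluorescence": np.column_stack([session.f_signal, session.f_control]).ravel(),
        }
    )
    header = (
        f"# rate_hz={session.rate_hz!r} site_id={session.site_id} "
        f"subject_id={session.subject_id}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_session_csv(path: Path) -> PhotometrySession:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _SESSION_COLS, "session CSV")
    bad = df.index[df["fluorescence"].isna()]
    if len(bad):
        raise ValidationError(f"session CSV: NaN fluorescence at row {bad[0]}")
    parts = {}
    for channel, grp in df.groupby("channel"):
        parts[channel] = grp.sort_values("time_s")
    if set(parts) != {"signal", "control"}:
        raise ValidationError(f"session CSV: expected channels signal/control, got {sorted(parts)}")
    sig, ctl = parts["signal"], parts["control"]
    if len(sig) != len(ctl):
        raise ValidationError(
            f"session CSV: deinterleaved channel lengths differ "
            f"(signal {len(sig)}, control {len(ctl)}); dropped frame?"
        )
    time = sig["time_s"].to_numpy()
    if not np.allclose(time, ctl["time_s"].to_numpy()):
        raise ValidationError("session CSV: channel timestamps do not align")
    rate = float(meta.get("rate_hz", "0").strip("'\"") or 0)
    if rate <= 0:
        dt = np.diff(time)
        rate = 1.0 / float(np.median(dt)) if len(dt) else 0.0
    return PhotometrySession(
        time_s=time,
        f_signal=sig["fluorescence"].to_numpy(),
        f_control=ctl["fluorescence"].to_numpy(),
        rate_hz=rate,
        site_id=meta.get("site_id", "RE"),
        subject_id=meta.get("subject_id", "subject"),
    )


def read_session(path: str | Path) -> PhotometrySession:
    """Load and validate a photometry session (CSV or HDF5, by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("time_s", "signal", "control"):
                if name not in f:
                    raise ValidationError(f"session HDF5: missing dataset /{name}")
            return PhotometrySession(
                time_s=f["time_s"][:],
                f_signal=f["signal"][:],
                f_control=f["control"][:],
                rate_hz=float(f.attrs.get("rate_hz", 10.0)),
                site_id=str(f.attrs.get("site_id", "RE")),
                subject_id=str(f.attrs.get("subject_id", "subject")),
            )
    return _read_session_csv(path)


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"onset_s": e.onset_s, "offset_s": e.offset_s, "kind": e.kind,
             "trial_index": e.trial_index}
            for e in schedule.events
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> EventSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["onset_s", "offset_s", "kind", "trial_index"], "events CSV")
    if df.empty:
        raise ValidationError("no events")
    events = [
        Event(float(r.onset_s), float(r.offset_s), str(r.kind), int(r.trial_index))
        for r in df.itertuples()
    ]
    return EventSchedule(events)  # sorts on construction


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={traj.frame_rate_hz!r}\n")
        pd.DataFrame({"time_s": traj.time_s, "x": traj.x, "y": traj.y}).to_csv(
            fh, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    rate = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("frame_rate_hz="):
                    rate = float(tok.split("=", 1)[1].strip("'\""))
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "x", "y"], "trajectory CSV")
    if df.empty:
        raise ValidationError("empty trajectory")
    t = df["time_s"].to_numpy(float)
    if rate <= 0:
        dt = np.diff(t)
        rate = 1.0 / float(np.median(dt)) if len(dt) else 0.0
    return Trajectory(time_s=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
                      frame_rate_hz=rate)


def write_cells(cells: list[CellRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"region": c.region, "ap_mm": c.ap_mm, "ml_um": c.ml_um, "label": c.label}
         for c in cells]
    ).to_csv(path, index=False, float_format="%.17g")


def read_cells(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["region", "ap_mm", "ml_um", "label"], "cells CSV")
    if df.empty:
        raise ValidationError("empty cell table")
    return [
        CellRecord(region=str(r.region), ap_mm=float(r.ap_mm), ml_um=float(r.ml_um),
                   label=str(r.label))
        for r in df.itertuples()
    ]
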