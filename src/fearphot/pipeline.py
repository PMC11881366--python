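"""End-to-end workflow: simulate (or load) a cohort, preprocess, quantify
peri-CS windows, and run the session's statistical battery.

The pipeline is deliberately declarative: one config dict (or YAML file)
names either a simulation block (day type, cohort size, response profile,
seed) or explicit input files, and every stage writes tidy CSVs so each
step can be re-run or inspected independently. Re-running with the same
config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, formats, preprocess, quantify, simulate, stats
from .core import (
    CS_MINUS,
    CS_PLUS,
    PHASE_CS_MINUS,
    PHASE_CS_PLUS_E,
    PHASE_CS_PLUS_L,
    WINDOWS,
    NoiseModel,
    ResponseProfile,
    TrialMatrix,
    ValidationError,
)

PHASES = (PHASE_CS_MINUS, PHASE_CS_PLUS_E, PHASE_CS_PLUS_L)


def _profile_for(day: str, name: str | ResponseProfile) -> ResponseProfile:
    if isinstance(name, ResponseProfile):
        return name
    n_plus = {"conditioning": 5, "extinction": 30, "retrieval": 10}.get(day, 0)
    if name == "null":
        return simulate.null_profile()
    if name == "biphasic":
        return simulate.biphasic_extinction_profile(n_cs_plus=max(n_plus, 1))
    if name == "conditioning":
        # CS+ response developing over learning, strong US response
        curve = tuple(np.linspace(0.2, 1.0, max(n_plus, 1)))
        return ResponseProfile(cs_plus_onset_amp=1.5, us_amp=3.0,
                               offset_suppression_amp=0.0, learning_curve=curve)
    raise ValidationError(f"unknown profile {name!r}")


def simulate_cohort(
    day: str,
    n_subjects: int = 7,
    profile: str | ResponseProfile = "biphasic",
    noise: NoiseModel | None = None,
    seed: int = 0,
    site_id: str = "RE",
):
    """Simulate one session per subject; schedules and noise draws differ
    per subject through seeds derived from ``seed``."""
    noise = noise or NoiseModel()
    prof = _profile_for(day, profile)
    out = []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        schedule = simulate.make_schedule(day, seed=sub_seed)
        session = simulate.simulate_session(
            schedule, prof, noise, seed=sub_seed,
            site_id=site_id, subject_id=f"m{i + 1:02d}",
        )
        out.append((session, schedule))
    return out


def quantify_cohort(
    cohort,
    session_name: str = "session",
    windows: tuple[str, ...] = tuple(WINDOWS),
) -> pd.DataFrame:
    """Preprocess every subject and emit the tidy per-trial window table."""
    records = []
    matrices = []
    for session, schedule in cohort:
        tm = preprocess.preprocess_session(session, schedule, session_name=session_name)
        matrices.append(tm)
        for w in windows:
            records.extend(quantify.window_auc(tm, w))
    df = quantify.records_frame(records)
    return df, matrices


def phase_table(df: pd.DataFrame, window: str, block_size: int = 5) -> pd.DataFrame:
    """Subjects x phases (CS-, CS+E, CS+L) table of AUC values for one window."""
    records = [
        quantify.AUCRecord(**row)
        for row in df[df["window"] == window].to_dict("records")
    ]
    blocked = quantify.records_frame(quantify.block_trials(records, block_size))
    wide = blocked.pivot_table(index="subject_id", columns="phase", values="value")
    cols = [p for p in PHASES if p in wide.columns]
    return wide[cols]


def analyze_extinction(df: pd.DataFrame) -> dict[str, dict]:
    """Per-window one-way RM ANOVA (GG-corrected) across the three phases,
    with Tukey post-hoc contrasts — the extinction-session battery."""
    out = {}
    for window in df["window"].unique():
        table = phase_table(df, window)
        res = stats.rm_anova_one_way(table.to_numpy(), posthoc="tukey")
        contrasts = {}
        if res.posthoc:
            names = list(table.columns)
            for ph in res.posthoc:
                i, j = ph["contrast"]
                contrasts[f"{names[i]} vs {names[j]}"] = ph["p_adj"]
        out[window] = {"anova": res, "tukey": contrasts, "phases": list(table.columns)}
    return out


def analyze_conditioning(df: pd.DataFrame) -> dict:
    """Conditioning-session battery.

    onset10: normality-gated paired comparison of per-subject mean CS+ vs
    CS- AUC, plus the 2 x 5 (CS type x trial) two-way RM ANOVA; offset5:
    gated paired comparison (the post-offset window contains the US
    response on CS+ trials).
    """
    out = {}
    for window in ("onset10", "offset5"):
        sub = df[df["window"] == window]
        wide = sub.pivot_table(index="subject_id", columns="kind", values="value")
        out[window] = {
            "paired": stats.select_test(wide[CS_PLUS].to_numpy(), wide[CS_MINUS].to_numpy())
        }
    # trial-course interaction: subjects x CS type x trial number
    sub = df[df["window"] == "onset10"]
    cube = (
        sub.pivot_table(index="subject_id", columns=["kind", "trial_index"], values="value")
        .sort_index(axis=1)
    )
    kinds = sorted({k for k, _ in cube.columns})
    trials = sorted({t for _, t in cube.columns})
    arr = np.stack(
        [cube[k][trials].to_numpy() for k in kinds], axis=1
    )  # subjects x kind x trial
    out["trial_course"] = stats.rm_anova_two_way(arr)
    return out


def freezing_cohort(
    day: str,
    n_subjects: int = 7,
    freeze_by_kind: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate trajectories with planted per-CS freezing fractions and
    score them; returns tidy per-event percentages."""
    freeze_by_kind = freeze_by_kind or {CS_PLUS: 0.7, CS_MINUS: 0.2}
    rows = []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        schedule = simulate.make_schedule(day, seed=sub_seed)
        epochs = []
        for ev in schedule.cs_events():
            frac = freeze_by_kind.get(ev.kind, 0.0)
            if frac > 0:
                epochs.append((ev.onset_s, ev.onset_s + frac * ev.duration_s))
        traj = simulate.simulate_trajectory(
            epochs, duration_s=schedule.duration_s + 30.0, seed=sub_seed
        )
        energy = behavior.motion_energy(traj)
        detected = behavior.detect_freezing(energy, traj.frame_rate_hz)
        _, per_event = behavior.percent_freezing(detected, schedule)
        for r in per_event:
            rows.append({"subject_id": f"m{i + 1:02d}", **r})
    return pd.DataFrame(rows)


def _stat_row(name: str, res: stats.StatResult) -> dict:
    return {
        "test": name,
        "kind": res.test,
        "statistic": round(res.statistic, 6),
        "df1": round(res.df[0], 4) if res.df else None,
        "df2": round(res.df[1], 4) if res.df and len(res.df) > 1 else None,
        "epsilon": round(res.epsilon, 4) if res.epsilon is not None else None,
        "p": round(res.p, 6),
        "note": res.note,
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured workflow and write tidy outputs.

    Config keys: ``seed`` (int), ``day`` (session type), ``n_subjects``,
    ``profile`` (null | biphasic | conditioning), ``stages`` (subset of
    simulate, quantify, stats, freezing), ``out_dir``. Returns a report
    dict; CSVs and ``report.json`` land in ``out_dir`` when given.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    day = config.get("day", "extinction")
    n_subjects = int(config.get("n_subjects", 7))
    profile = config.get("profile", "biphasic")
    stages = config.get("stages", ["simulate", "quantify", "stats", "freezing"])
    out_dir = Path(out_dir or config.get("out_dir", "fearphot_out"))

    report: dict = {"config": {"seed": seed, "day": day, "n_subjects": n_subjects,
                               "profile": str(profile), "stages": list(stages)}}
    df = None
    if "simulate" in stages or "quantify" in stages:
        cohort = simulate_cohort(day, n_subjects, profile, seed=seed)
        df, _ = quantify_cohort(cohort, session_name=day)
    if df is not None and "stats" in stages:
        rows = []
        if day == "conditioning":
            cond = analyze_conditioning(df)
            for w in ("onset10", "offset5"):
                rows.append(_stat_row(f"{w}: CS+ vs CS-", cond[w]["paired"]))
            tc = cond["trial_course"]
            rows.append(_stat_row("onset10 trial-course: CS type", tc.main_a))
            rows.append(_stat_row("onset10 trial-course: trial", tc.main_b))
            rows.append(_stat_row("onset10 trial-course: interaction", tc.interaction))
            report["conditioning"] = rows
        else:
            ext = analyze_extinction(df)
            for w, res in ext.items():
                rows.append(_stat_row(f"{w}: phase RM-ANOVA", res["anova"]))
            report["extinction"] = rows
            report["tukey"] = {w: res["tukey"] for w, res in ext.items()}
        report["stats_rows"] = rows
    freeze_df = None
    if "freezing" in stages:
        freeze_df = freezing_cohort(day, n_subjects, seed=seed)
        report["freezing_mean_percent"] = {
            k: round(float(v), 3)
            for k, v in freeze_df.groupby("kind")["percent"].mean().items()
        }

    out_dir.mkdir(parents=True, exist_ok=True)
    if df is not None:
        df.to_csv(out_dir / "quantification.csv", index=False)
    if "stats_rows" in report:
        pd.DataFrame(report["stats_rows"]).to_csv(out_dir / "stats.csv", index=False)
    if freeze_df is not None:
        freeze_df.to_csv(out_dir / "freezing.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def demo_config(seed: int = 7) -> dict:
    """The one-command synthetic demo: an extinction cohort of 7 subjects
    with the biphasic planted profile."""
    return {
        "seed": seed,
        "day": "extinction",
        "n_subjects": 7,
        "profile": "biphasic",
        "stages": ["simulate", "quantify", "stats", "freezing"],
    }
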