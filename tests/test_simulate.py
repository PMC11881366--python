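"""Synthetic-data generator: schedule layouts, forward-model oracles,
trajectory and cell-map parameter recovery."""

import numpy as np
import pytest

import fearphot as fp
from fearphot.core import CS_MINUS, CS_PLUS, LASER, US, NoiseModel, ValidationError
from fearphot import simulate as sim

from conftest import corrected_from_clean


# ---------------------------------------------------------------- schedules

def test_conditioning_layout_and_us_pairing():
    sch = sim.make_schedule("conditioning", seed=3)
    counts = sch.counts()
    assert counts[CS_MINUS] == 5 and counts[CS_PLUS] == 5 and counts[US] == 5
    plus = {e.trial_index: e for e in sch.of_kind(CS_PLUS)}
    for us in sch.of_kind(US):
        assert us.onset_s == plus[us.trial_index].offset_s  # US starts at CS+ offset
        assert us.duration_s == pytest.approx(2.0)
    for cs in sch.cs_events():
        assert cs.duration_s == pytest.approx(20.0)


@pytest.mark.parametrize(
    "day,expected",
    [
        ("habituation", {CS_MINUS: 30}),
        ("extinction", {CS_MINUS: 5, CS_PLUS: 30}),
        ("retrieval", {CS_MINUS: 5, CS_PLUS: 10}),
        ("opto_retrieval", {CS_PLUS: 6}),
    ],
)
def test_day_event_counts(day, expected):
    assert sim.make_schedule(day, seed=1).counts() == expected


def test_schedule_iti_bounds_and_sorting():
    sch = sim.make_schedule("extinction", seed=9)
    cs = sch.cs_events()
    onsets = [e.onset_s for e in cs]
    assert onsets == sorted(onsets)
    gaps = np.diff(onsets) - 20.0  # offset-to-next-onset
    assert np.all(gaps >= 50.0 - 1e-9) and np.all(gaps <= 90.0 + 1e-9)


def test_schedule_interleaving_minority_run_cap():
    sch = sim.make_schedule("extinction", seed=5)
    kinds = [e.kind for e in sch.cs_events()]
    run = 0
    for k in kinds:
        run = run + 1 if k == CS_MINUS else 0
        assert run <= 2


def test_opto_laser_windows():
    inh = sim.make_schedule("opto_extinction", seed=2, laser_mode="inhibition")
    cs = inh.of_kind(CS_PLUS)
    lasers = inh.of_kind(LASER)
    assert len(lasers) == len(cs) == 30
    for c, l in zip(cs, sorted(lasers, key=lambda e: e.onset_s)):
        assert l.onset_s == pytest.approx(c.onset_s - 0.4)
        assert l.offset_s == pytest.approx(c.offset_s + 3.0)
    act = sim.make_schedule("opto_retrieval", seed=2, laser_mode="activation")
    for c, l in zip(act.of_kind(CS_PLUS), act.of_kind(LASER)):
        assert (l.onset_s, l.offset_s) == (c.onset_s, c.offset_s)


def test_schedule_determinism_and_bad_day():
    a = sim.make_schedule("conditioning", seed=11)
    b = sim.make_schedule("conditioning", seed=11)
    assert [(e.onset_s, e.kind) for e in a.events] == [(e.onset_s, e.kind) for e in b.events]
    with pytest.raises(ValidationError):
        sim.make_schedule("day5")
    with pytest.raises(ValidationError):
        sim.ScheduleParams(cs_duration_s=-1.0)


# ------------------------------------------------------------ photometry

def test_session_determinism(single_cs_schedule):
    prof = fp.ResponseProfile(learning_curve=(1.0,))
    a = sim.simulate_session(single_cs_schedule, prof, NoiseModel(), seed=4)
    b = sim.simulate_session(single_cs_schedule, prof, NoiseModel(), seed=4)
    assert np.array_equal(a.f_signal, b.f_signal)
    assert np.array_equal(a.f_control, b.f_control)


def test_null_profile_zero_zscores(single_cs_schedule, quiet_noise):
    """All amplitudes zero, all noise off: downstream z is identically 0."""
    sess = sim.simulate_session(single_cs_schedule, sim.null_profile(), quiet_noise, seed=0)
    assert np.allclose(sess.f_signal, sess.f_signal[0])
    trace = corrected_from_clean(sess)
    assert np.allclose(trace.value, 0.0, atol=1e-12)


def test_planted_kernel_auc_matches_closed_form(single_cs_schedule, quiet_noise):
    """Noise-free planted onset transient: the onset-window AUC equals the
    closed-form kernel integral, itself checked against fine-grid quadrature."""
    amp = 2.3
    prof = fp.ResponseProfile(
        cs_plus_onset_amp=amp, cs_minus_amp=0.0, us_amp=0.0,
        offset_suppression_amp=0.0, learning_curve=(1.0,),
    )
    sess = sim.simulate_session(single_cs_schedule, prof, quiet_noise, seed=0)
    tm = fp.preprocess.align_trials(
        corrected_from_clean(sess), single_cs_schedule, normalize=False
    )
    rec = [r for r in fp.quantify.window_auc(tm, "onset10") if r.kind == CS_PLUS][0]
    expected = amp * sim.kernel_integral(prof.transient_rise_s, prof.transient_decay_s, 10.0)
    # closed form vs fine-grid numerical integral of the kernel
    t_fine = np.linspace(0, 10, 200_001)
    numeric = amp * np.trapezoid(
        sim.transient_kernel(t_fine, prof.transient_rise_s, prof.transient_decay_s), t_fine
    )
    assert expected == pytest.approx(numeric, rel=1e-6)
    assert rec.value == pytest.approx(expected, rel=0.01)


def test_planted_amplitude_monotonicity(single_cs_schedule, quiet_noise):
    """Larger planted onset amplitude -> larger measured onset AUC."""
    aucs = []
    for amp in (0.5, 1.0, 1.5, 2.0, 2.5):
        prof = fp.ResponseProfile(
            cs_plus_onset_amp=amp, us_amp=0.0, offset_suppression_amp=0.0,
            learning_curve=(1.0,),
        )
        sess = sim.simulate_session(single_cs_schedule, prof, quiet_noise, seed=0)
        tm = fp.preprocess.align_trials(
            corrected_from_clean(sess), single_cs_schedule, normalize=False
        )
        rec = [r for r in fp.quantify.window_auc(tm, "onset10") if r.kind == CS_PLUS][0]
        aucs.append(rec.value)
    assert np.all(np.diff(aucs) > 0)


def test_null_profile_no_false_structure():
    """Null-response cohort: |mean z| < 0.1 in every window over 20 subjects."""
    means = {w: [] for w in fp.core.WINDOWS}
    for i in range(20):
        sch = sim.make_schedule("retrieval", seed=300 + i)
        sess = sim.simulate_session(sch, sim.null_profile(), NoiseModel(), seed=600 + i)
        tm = fp.preprocess.preprocess_session(sess, sch)
        for w in means:
            recs = fp.quantify.window_auc(tm, w)
            means[w].append(np.mean([r.mean_z for r in recs]))
    for w, vals in means.items():
        assert abs(np.mean(vals)) < 0.1, f"window {w} biased: {np.mean(vals):.3f}"


def test_session_guards(single_cs_schedule):
    prof = fp.ResponseProfile(learning_curve=(1.0,))
    with pytest.raises(ValidationError):
        sim.simulate_session(single_cs_schedule, prof, NoiseModel(), rate_hz=-1)
    with pytest.raises(ValidationError, match="learning_curve"):
        sim.simulate_session(
            single_cs_schedule,
            fp.ResponseProfile(learning_curve=(1.0, 0.5)),
            NoiseModel(),
        )


# ------------------------------------------------------------ trajectories

def test_trajectory_frozen_everywhere_is_stationary():
    traj = sim.simulate_trajectory([(0.0, 10.0)], 10.0, jitter=0.0, seed=1)
    assert np.ptp(traj.x) == 0 and np.ptp(traj.y) == 0


def test_trajectory_free_motion_scale():
    traj = sim.simulate_trajectory([], 100.0, move_speed=2.0, seed=2)
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    # mean |step| of a 2-D Gaussian with per-axis SD 2 is 2*sqrt(pi/2)
    assert steps.mean() == pytest.approx(2.0 * np.sqrt(np.pi / 2), rel=0.1)


def test_trajectory_epoch_recovery_within_two_frames():
    epochs = [(20.0, 35.0), (50.0, 62.0)]
    traj = sim.simulate_trajectory(epochs, 80.0, seed=3)
    energy = fp.behavior.motion_energy(traj)
    found = fp.behavior.detect_freezing(energy, traj.frame_rate_hz, threshold=15.0)
    assert len(found) == len(epochs)
    tol = 2.0 / traj.frame_rate_hz
    for (s0, e0), (s1, e1) in zip(epochs, found):
        assert abs(s0 - s1) <= tol + 1e-9
        assert abs(e0 - e1) <= tol + 1e-9


def test_trajectory_guards():
    with pytest.raises(ValidationError, match="overlap"):
        sim.simulate_trajectory([(0, 5), (4, 8)], 10.0)
    with pytest.raises(ValidationError):
        sim.simulate_trajectory([], 10.0, frame_rate_hz=-30)


# --------------------------------------------------------------- cell maps

def test_cellmap_null_separation():
    centers = {"dmPFC": (-0.8, 300.0), "vmPFC": (-0.8, 300.0)}
    spreads = {"dmPFC": (0.2, 80.0), "vmPFC": (0.2, 80.0)}
    cells = sim.simulate_cellmap({"dmPFC": 300, "vmPFC": 300}, centers, spreads, seed=4)
    st = fp.tracing.ml_distance_stats(cells, "RE", labels=("dmPFC", "vmPFC"))
    diff = abs(st["dmPFC"]["mean_ml_um"] - st["vmPFC"]["mean_ml_um"])
    se = np.hypot(st["dmPFC"]["sem"], st["vmPFC"]["sem"])
    assert diff < 3 * se


def test_cellmap_planted_center_recovery():
    centers = {"dmPFC": (-0.8, 500.0), "vmPFC": (-0.8, 200.0)}
    spreads = {"dmPFC": (0.2, 60.0), "vmPFC": (0.2, 60.0)}
    cells = sim.simulate_cellmap({"dmPFC": 200, "vmPFC": 200}, centers, spreads, seed=5)
    st = fp.tracing.ml_distance_stats(cells, "RE", labels=("dmPFC", "vmPFC"))
    for label, (_, ml0) in centers.items():
        assert abs(st[label]["mean_ml_um"] - ml0) <= 3 * st[label]["sem"] + 1e-9
    assert st["vmPFC"]["mean_ml_um"] < st["dmPFC"]["mean_ml_um"]


def test_cellmap_both_fraction_zero_and_determinism():
    centers = {"vmPFC": (-0.8, 200.0)}
    spreads = {"vmPFC": (0.2, 60.0)}
    cells = sim.simulate_cellmap({"vmPFC": 100}, centers, spreads, both_fraction=0.0, seed=6)
    assert fp.tracing.overlap_ratio(cells, "RE", "vmPFC") == 0.0
    again = sim.simulate_cellmap({"vmPFC": 100}, centers, spreads, both_fraction=0.0, seed=6)
    assert [(c.ap_mm, c.ml_um) for c in cells] == [(c.ap_mm, c.ml_um) for c in again]
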