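import numpy as np
import pytest

import fearphot as fp
from fearphot.core import Event, EventSchedule, NoiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def single_cs_schedule():
    """One CS+ and one CS- with onsets exactly on the 10 Hz grid."""
    return EventSchedule([
        Event(40.0, 60.0, "CS_PLUS", 0),
        Event(140.0, 160.0, "CS_MINUS", 0),
    ])


@pytest.fixture
def quiet_noise():
    """No stochastic terms and no bleaching: signal = baseline + transients."""
    return NoiseModel(white_sd=0.0, motion_sd=0.0, bleach_frac=0.0)


def corrected_from_clean(session):
    """Corrected trace for a noise-free session, bypassing the OLS fit
    (which is degenerate when the control channel is constant)."""
    return fp.CorrectedTrace(
        time_s=session.time_s,
        value=session.f_signal - session.f_signal[0],
        fit_slope=0.0,
        fit_intercept=float(session.f_signal[0]),
        rate_hz=session.rate_hz,
    )
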