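"""QRS feature extraction, activation maps, physiological classification."""

import numpy as np
import pytest

from hearts import qrs
from hearts.ecg import ECGTrace
from hearts.errors import (AmbiguityError, ConfigurationError,
                           NoQRSDetectedError, ParameterError)


def _ramp(t, knots):
    """Piecewise-linear series through (time, value) knots."""
    times = [k[0] for k in knots]
    vals = [k[1] for k in knots]
    return np.interp(t, times, vals)


def _trace(lead1, lead2, t):
    return ECGTrace(time_ms=t, lead_i=lead1, lead_ii=lead2,
                    lead_iii=lead2 - lead1)


@pytest.fixture
def synthetic_beat():
    """Lead I: -0.1 mV dip, +1.2 mV peak, return; lead II adds a -0.3 mV
    trailing dip."""
    t = np.arange(0.0, 400.0, 1.0)
    lead1 = _ramp(t, [(0, 0), (99, 0), (105, -0.1), (115, 1.2), (130, 0),
                      (400, 0)])
    lead2 = _ramp(t, [(0, 0), (99, 0), (113, 0.9), (120, 0), (124, -0.3),
                      (129, 0), (400, 0)])
    return _trace(lead1, lead2, t)


def test_amplitudes_from_constructed_waveform(synthetic_beat):
    f = qrs.extract_features(synthetic_beat)
    assert f.q_amp_mv == pytest.approx(0.1, abs=0.02)
    assert f.r_amp_mv == pytest.approx(1.2, abs=0.02)
    assert f.s_amp_mv == pytest.approx(0.3, abs=0.02)


def test_duration_tracks_deflection_span():
    """The envelope window adds a constant overhang, so durations of two
    beats whose deflection spans differ by 40 ms differ by 40 ms, and each
    covers at least its nominal span."""
    t = np.arange(0.0, 400.0, 1.0)

    def beat(span):
        knots = [(0, 0), (100, 0), (100 + span / 4, 1.0),
                 (100 + span / 2, -0.2), (100 + 3 * span / 4, 0.4),
                 (100 + span, 0), (400, 0)]
        lead1 = _ramp(t, knots)
        return qrs.extract_features(_trace(lead1, lead1.copy(), t))

    d80 = beat(80.0).qrs_duration_ms
    d120 = beat(120.0).qrs_duration_ms
    assert d80 >= 80.0 and d120 >= 120.0
    assert d120 - d80 == pytest.approx(40.0, abs=3.0)


def test_flat_trace_raises(synthetic_beat):
    t = synthetic_beat.time_ms
    with pytest.raises(NoQRSDetectedError):
        qrs.extract_features(_trace(np.zeros_like(t), np.zeros_like(t), t))


def test_two_beats_raise_ambiguity():
    t = np.arange(0.0, 1000.0, 1.0)
    one = _ramp(t, [(0, 0), (99, 0), (105, -0.1), (115, 1.2), (130, 0),
                    (1000, 0)])
    two = one + _ramp(t, [(0, 0), (599, 0), (605, -0.1), (615, 1.2),
                          (630, 0), (1000, 0)])
    with pytest.raises(AmbiguityError):
        qrs.extract_features(_trace(two, two.copy(), t))


def test_s_wave_duration_measures_terminal_negativity():
    """Widening the terminal negative deflection of lead I by 40 ms widens
    the reported S-wave duration by 40 ms (the window overhang cancels)."""
    t = np.arange(0.0, 400.0, 1.0)

    def beat(s_span):
        lead1 = _ramp(t, [(0, 0), (100, 0), (110, 1.0), (120, 0),
                          (121, -0.25), (120 + s_span - 5, -0.2),
                          (120 + s_span, 0), (400, 0)])
        return qrs.extract_features(_trace(lead1, lead1.copy(), t))

    short = beat(20.0).s_duration_ms
    long = beat(60.0).s_duration_ms
    assert long >= 60.0
    assert long - short == pytest.approx(40.0, abs=3.0)


# --- activation maps ---

def test_stimulated_voxels_activate_at_onset(beat_runner, iars, heart):
    res, _ = beat_runner("4")
    amap = qrs.activation_map(res)
    for name in iars:
        seed_at = amap.times_ms[iars.seed(name)]
        onset = 5.0 if name == "RAIW" else 0.0
        assert onset <= seed_at <= onset + 2.0, name


def test_four_early_islands_on_iars(beat_runner, iars):
    """Healthy 4-seed beat: earliest activation inside every IAR mask is
    within the first 10 ms."""
    res, _ = beat_runner("4")
    amap = qrs.activation_map(res)
    for name in iars:
        earliest = np.nanmin(amap.times_ms[iars.mask(name)])
        assert earliest <= 10.0, name


def test_threshold_out_of_range_rejected(beat_runner):
    res, _ = beat_runner("4")
    with pytest.raises(ParameterError):
        qrs.activation_map(res, threshold_mv=100.0)


def test_recomputed_threshold_close_to_solver_record(beat_runner):
    """Recomputing the map from snapshots at a different threshold gives
    times close to (and ordered like) the solver's sub-dt record."""
    res, _ = beat_runner("4")
    a = qrs.activation_map(res)                      # solver record, 0 mV
    b = qrs.activation_map(res, threshold_mv=-20.0)  # from snapshots
    mask = np.isfinite(a.times_ms)
    assert np.isfinite(b.times_ms[mask]).all()
    # -20 mV is crossed during the same upstroke, at most ~2 ms earlier
    diff = a.times_ms[mask] - b.times_ms[mask]
    assert np.nanmax(np.abs(diff)) < 3.0


def test_never_activated_voxels_undefined():
    from hearts.slab import make_slab
    from hearts import solver as so
    geom, fibers = make_slab((10, 3, 3), 2.5)
    res = so.run_simulation(geom, fibers, None,
                            so.SolverParams(duration_ms=5.0))
    amap = qrs.activation_map(res)
    assert not amap.defined_mask().any()


# --- physiological classification ---

def test_value_on_bound_is_within():
    f = qrs.QRSFeatures(q_amp_mv=0.0, r_amp_mv=2.0, s_amp_mv=0.9,
                        qrs_duration_ms=110.0, s_duration_ms=0.0,
                        onset_ms=0.0, offset_ms=110.0)
    flags = qrs.classify_physiological(f)
    assert flags["QRSd_ms"][0] and flags["Ramp_mV"][0] and flags["Samp_mV"][0]


def test_value_above_bound_reports_exceedance():
    f = qrs.QRSFeatures(q_amp_mv=0.1, r_amp_mv=1.0, s_amp_mv=0.2,
                        qrs_duration_ms=130.0, s_duration_ms=0.0,
                        onset_ms=0.0, offset_ms=130.0)
    within, dist = qrs.classify_physiological(f)["QRSd_ms"]
    assert not within and dist == pytest.approx(20.0)


def test_empty_or_missing_ranges_rejected():
    f = qrs.QRSFeatures(0.1, 1.0, 0.2, 90.0, 0.0, 0.0, 90.0)
    with pytest.raises(ConfigurationError):
        qrs.classify_physiological(f, qrs.PhysiologicalRanges(bounds={}))
    with pytest.raises(ConfigurationError):
        qrs.classify_physiological(
            f, qrs.PhysiologicalRanges(bounds={"QRSd_ms": (60.0, 110.0)}))


def test_invalid_range_rejected():
    with pytest.raises(ConfigurationError):
        qrs.PhysiologicalRanges(bounds={"QRSd_ms": (110.0, 60.0)})


# --- BBB morphology contract ---

def test_rbbb_prolongs_qrs_and_s_wave(beat_runner):
    """RBBB vs the healthy 12-stimulus beat on the same anatomy: strictly
    longer QRS and a strictly longer lead-I S wave (the slurred-S
    signature)."""
    _, tr_healthy = beat_runner("12S")
    _, tr_rbbb = beat_runner("RBBB")
    f_h = qrs.extract_features(tr_healthy)
    f_r = qrs.extract_features(tr_rbbb)
    assert f_r.qrs_duration_ms > f_h.qrs_duration_ms
    assert f_r.s_duration_ms > f_h.s_duration_ms
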