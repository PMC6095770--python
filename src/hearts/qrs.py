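"""QRS feature extraction, physiological classification, activation maps.

Feature conventions follow the study protocol: Q and R wave amplitudes and
the QRS duration are measured in lead I, the S wave amplitude in lead II;
amplitudes are reported as magnitudes (mV).  The QRS window comes from the
Pan-Tompkins construction: the squared lead-I derivative is integrated over
a 30 ms moving window and the onset/offset are the earliest/latest
sustained (5 ms) crossings of this energy envelope above a small fraction
of its beat maximum.  The fraction is deliberately tiny (0.01%) because
simulated traces are noise-free and the terminal activity of prolonged
beats is low-amplitude; a raw-derivative threshold truncates such tails
inconsistently between configurations.  The envelope window widens every
measured duration by a nearly constant ~30 ms, so differences and ranges
across configurations -- the quantities the sensitivity analysis uses --
are unaffected.  The S-wave duration in lead I runs from the start of the
terminal negative deflection to the QRS offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import ECGTrace
from .errors import (AmbiguityError, ConfigurationError, NoQRSDetectedError,
                     ParameterError)
from .solver import SimulationResult

#: Bundle-branch-block criteria (Chou): QRS duration > 120 ms and, for RBBB,
#: a slurred lead-I S wave longer than 40 ms.
QRS_DURATION_BBB_MS = 120.0
S_WAVE_BBB_MS = 40.0

#: Pan-Tompkins energy-envelope rule for the QRS window.
ENVELOPE_WINDOW_MS = 30.0
ENVELOPE_FRACTION = 1e-4
ONSET_PERSISTENCE_MS = 5.0


@dataclass
class QRSFeatures:
    """Q/R amplitudes and durations from lead I, S amplitude from lead II."""

    q_amp_mv: float
    r_amp_mv: float
    s_amp_mv: float
    qrs_duration_ms: float
    s_duration_ms: float
    onset_ms: float
    offset_ms: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Qamp_mV": self.q_amp_mv, "Ramp_mV": self.r_amp_mv,
            "Samp_mV": self.s_amp_mv, "QRSd_ms": self.qrs_duration_ms,
            "Sdur_ms": self.s_duration_ms,
            "onset_ms": self.onset_ms, "offset_ms": self.offset_ms,
        }


FEATURE_NAMES = ("QRSd_ms", "Qamp_mV", "Ramp_mV", "Samp_mV")


@dataclass
class PhysiologicalRanges:
    """Inclusive [lower, upper] normal bounds per feature, in feature units."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(
        DEFAULT_NORMAL_BOUNDS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigurationError(
                    f"range for {name} must satisfy lower < upper")


#: Normal QRS bounds (textbook electrocardiography values): duration 60-110 ms
#: in adults; lead-I Q up to 0.3 mV; lead-I R 0.3-2.0 mV; lead-II S up to 0.9 mV.
DEFAULT_NORMAL_BOUNDS = {
    "QRSd_ms": (60.0, 110.0),
    "Qamp_mV": (0.0, 0.3),
    "Ramp_mV": (0.3, 2.0),
    "Samp_mV": (0.0, 0.9),
}


def _sustained_runs(above: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """[start, end) index ranges of runs of True of at least ``min_len``."""
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(above) - start >= min_len:
        runs.append((start, len(above)))
    return runs


def _energy_envelope(lead: np.ndarray, dt: float) -> np.ndarray:
    deriv = np.gradient(lead, dt)
    w = max(1, int(round(ENVELOPE_WINDOW_MS / dt)))
    return np.convolve(deriv ** 2, np.ones(w) / w, mode="same")


def _qrs_window(lead: np.ndarray, dt: float) -> tuple[int, int]:
    """Onset/offset sample indices: sustained crossings of the integrated
    squared-derivative envelope above ENVELOPE_FRACTION of its maximum."""
    env = _energy_envelope(lead, dt)
    emax = env.max()
    if emax <= 0:
        raise NoQRSDetectedError("flat trace: no QRS found")
    above = env >= ENVELOPE_FRACTION * emax
    min_len = max(1, int(round(ONSET_PERSISTENCE_MS / dt)))
    runs = _sustained_runs(above, min_len)
    if not runs:
        raise NoQRSDetectedError("no sustained depolarization deflection")
    return runs[0][0], runs[-1][1] - 1


def _count_beats(lead: np.ndarray, dt: float) -> int:
    """Pan-Tompkins-style beat count: energy-envelope peaks above 20% of
    maximum separated by > 300 ms."""
    env = _energy_envelope(lead, dt)
    thr = 0.2 * env.max()
    above = env > thr
    runs = _sustained_runs(above, 1)
    if not runs:
        return 0
    merged = [list(runs[0])]
    gap = int(round(300.0 / dt))
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return len(merged)


def extract_features(trace: ECGTrace) -> QRSFeatures:
    """QRS features of a single simulated beat.

    Raises NoQRSDetectedError on a flat trace and AmbiguityError if the
    energy envelope finds more than one beat.
    """
    dt = trace.dt_ms
    lead1 = trace.lead_i
    if np.abs(lead1).max() < 1e-9:
        raise NoQRSDetectedError("flat trace: no QRS found")
    n_beats = _count_beats(lead1, dt)
    if n_beats > 1:
        raise AmbiguityError(f"{n_beats} beats found; expected a single beat")

    i_on, i_off = _qrs_window(lead1, dt)
    t = trace.time_ms
    window1 = lead1[i_on:i_off + 1]
    i_r = i_on + int(np.argmax(window1))
    r_amp = max(0.0, float(lead1[i_r]))
    q_amp = max(0.0, -float(lead1[i_on:i_r + 1].min()))
    s_amp = max(0.0, -float(trace.lead_ii[i_r:i_off + 1].min()))

    # terminal negative deflection of lead I: last downward zero crossing
    s_dur = 0.0
    seg = lead1[i_r:i_off + 1]
    neg = np.flatnonzero(seg < 0)
    if neg.size:
        first_neg = int(neg[0])
        # walk back to the zero crossing
        s_start = i_r + first_neg
        s_dur = float(t[i_off] - t[s_start])

    return QRSFeatures(
        q_amp_mv=q_amp, r_amp_mv=r_amp, s_amp_mv=s_amp,
        qrs_duration_ms=float(t[i_off] - t[i_on]),
        s_duration_ms=s_dur,
        onset_ms=float(t[i_on]), offset_ms=float(t[i_off]))


@dataclass
class ActivationMap:
    """Per-voxel first activation time (ms); NaN marks never-activated."""

    times_ms: np.ndarray
    threshold_mv: float

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.times_ms)


def activation_map(result: SimulationResult,
                   threshold_mv: float = 0.0) -> ActivationMap:
    """First upward crossing of ``threshold_mv`` per voxel.

    Uses the solver's sub-dt activation record when the threshold matches
    the one used during the run; otherwise recomputes from the Vm snapshots
    with linear interpolation between snapshot times.
    """
    if not -100.0 <= threshold_mv <= 60.0:
        raise ParameterError(
            f"threshold {threshold_mv} mV outside [-100, 60] mV")
    if threshold_mv == result.params.activation_threshold_mv:
        return ActivationMap(times_ms=result.activation_time_ms.copy(),
                             threshold_mv=threshold_mv)
    vm = result.vm_mv.astype(np.float64)
    t = result.time_ms
    n = vm.shape[1]
    at = np.full(n, np.nan)
    for s in range(1, len(t)):
        crossed = np.isnan(at) & (vm[s - 1] < threshold_mv) & (vm[s] >= threshold_mv)
        if crossed.any():
            frac = (threshold_mv - vm[s - 1, crossed]) / (
                vm[s, crossed] - vm[s - 1, crossed])
            at[crossed] = t[s - 1] + (t[s] - t[s - 1]) * frac
    vol = np.full(result.geometry.shape, np.nan)
    vol[tuple(result.tissue_ijk.T)] = at
    return ActivationMap(times_ms=vol, threshold_mv=threshold_mv)


def classify_physiological(features: QRSFeatures,
                           ranges: PhysiologicalRanges | None = None
                           ) -> dict[str, tuple[bool, float]]:
    """Per-feature (within_range, signed_distance_to_nearest_bound).

    Bounds are inclusive; the signed distance is negative inside the range
    (distance to the nearest bound) and positive outside (exceedance).
    """
    ranges = ranges or PhysiologicalRanges()
    if not ranges.bounds:
        raise ConfigurationError("empty physiological ranges table")
    values = features.as_dict()
    out: dict[str, tuple[bool, float]] = {}
    for name in FEATURE_NAMES:
        if name not in ranges.bounds:
            raise ConfigurationError(f"no physiological range for {name}")
        lo, hi = ranges.bounds[name]
        v = values[name]
        within = lo <= v <= hi
        if within:
            dist = -min(v - lo, hi - v)
        elif v < lo:
            dist = lo - v
        else:
            dist = v - hi
        out[name] = (within, float(dist))
    return out
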