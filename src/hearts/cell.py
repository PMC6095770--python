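"""Single-cell interface to the ten Tusscher-Panfilov 2006 ventricular model.

Provides the resting state per cell type, a one-step integrator with the
package-wide stimulus sign convention (positive current depolarizes), and a
convenience beat runner used for calibration and testing.  The tissue solver
bypasses this module and calls the shared numba kernels directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tt06
from .errors import IntegrationFailureError, ParameterError

CELL_TYPES = ("endo", "M", "epi")
_TYPE_CODE = {"endo": _tt06.ENDO, "M": _tt06.MID, "epi": _tt06.EPI}

#: Maximum step for the default scheme (forward Euler for Vm and
#: concentrations, exponential Rush-Larsen update for the gates), ms.
MAX_FORWARD_EULER_DT_MS = 0.02

#: Maximum stable step when the gates too are advanced by plain forward
#: Euler: the fast sodium activation gate has tau_m ~ 0.001 ms near rest,
#: so explicit stability requires dt < 2*tau_m.
MAX_PURE_EULER_DT_MS = 0.0015

# Quiescent steady state per cell type, obtained by integrating the published
# model unstimulated for 20 s at dt = 0.02 ms from the published initial
# conditions.  Order follows _tt06.STATE_NAMES.
_RESTING = {
    "endo": np.array([
        -86.34890854, 0.001351902884, 0.7742775001, 0.7742661723,
        0.0001802060702, 0.4828078569, 0.002986700452, 2.005447139e-08,
        0.9999914431, 2.904832295e-05, 0.9999235051, 0.9995634492,
        0.9999978303, 0.9980808125, 4.259601028e-05, 0.6747521901,
        9.50416005e-05, 7.369430534, 138.8540977,
    ]),
    "M": np.array([
        -86.34906376, 0.001351858115, 0.7742813846, 0.7742700575,
        0.0001802020745, 0.482809472, 0.002986667432, 2.005395256e-08,
        0.9999982742, 2.904772177e-05, 0.9999235068, 0.9995634589,
        0.9999978303, 0.9980808333, 4.259594709e-05, 0.6747510753,
        9.504053971e-05, 7.369434702, 138.8540941,
    ]),
    "epi": np.array([
        -86.34890854, 0.001351902882, 0.7742775002, 0.7742661725,
        0.00018020607, 0.482807857, 0.002986700451, 2.005447137e-08,
        0.9999982741, 2.904832292e-05, 0.9999235051, 0.9995634492,
        0.9999978303, 0.9980808125, 4.259601027e-05, 0.6747521901,
        9.504160045e-05, 7.369430534, 138.8540977,
    ]),
}


@dataclass
class CellParams:
    """Cell-type tag and the type-dependent conductances of the 2006 model.

    ``g_ks``/``g_to`` default to the published values for the tag; ``cm`` is
    the membrane capacitance in uF/cm^2 (it cancels in the reaction update
    because currents are expressed per unit capacitance).
    """

    cell_type: str = "epi"
    g_ks: float | None = None
    g_to: float | None = None
    cm: float = 1.0
    #: exponential (Rush-Larsen) gate update, as in the published model code.
    #: Setting this False selects plain forward Euler for the gates as well,
    #: which is only stable for dt below MAX_PURE_EULER_DT_MS.
    rush_larsen: bool = True

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ParameterError(
                f"unknown cell type {self.cell_type!r}; expected one of {CELL_TYPES}")
        code = _TYPE_CODE[self.cell_type]
        if self.g_ks is None:
            self.g_ks = _tt06.G_KS_BY_TYPE[code]
        if self.g_to is None:
            self.g_to = _tt06.G_TO_BY_TYPE[code]
        if self.g_ks < 0 or self.g_to < 0:
            raise ParameterError("conductances must be non-negative")

    @property
    def type_code(self) -> int:
        return _TYPE_CODE[self.cell_type]


@dataclass
class CellState:
    """State vector of one myocyte: Vm (mV), 12 gates, ionic concentrations (mM)."""

    values: np.ndarray = field(
        default_factory=lambda: _RESTING["epi"].copy())

    @property
    def Vm(self) -> float:
        return float(self.values[0])

    @property
    def gates(self) -> dict[str, float]:
        return {name: float(self.values[_tt06.STATE_NAMES.index(name)])
                for name in _tt06.GATE_NAMES}

    @property
    def concentrations(self) -> dict[str, float]:
        return {name: float(self.values[_tt06.STATE_NAMES.index(name)])
                for name in ("Cai", "CaSR", "Cass", "Nai", "Ki")}

    def as_dict(self) -> dict[str, float]:
        return dict(zip(_tt06.STATE_NAMES, map(float, self.values)))

    def copy(self) -> "CellState":
        return CellState(self.values.copy())


def initial_state(cell_type: str = "epi") -> CellState:
    """Return the quiescent steady state of the published model for a cell type."""
    if cell_type not in CELL_TYPES:
        raise ParameterError(
            f"unknown cell type {cell_type!r}; expected one of {CELL_TYPES}")
    return CellState(_RESTING[cell_type].copy())


def step_cell(state: CellState, istim: float, dt: float,
              params: CellParams | None = None) -> CellState:
    """Advance one cell by ``dt`` ms under stimulus current ``istim`` (uA/uF).

    Positive ``istim`` depolarizes.  Forward Euler is used unless
    ``params.rush_larsen`` requests exponential gate updates.
    """
    params = params or CellParams()
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    limit = MAX_FORWARD_EULER_DT_MS if params.rush_larsen else MAX_PURE_EULER_DT_MS
    if dt > limit:
        raise ParameterError(
            f"dt={dt} ms exceeds the stability bound {limit} ms for this scheme")
    new = state.copy()
    S = new.values.reshape(1, -1)
    _tt06.step_states(
        S, np.array([float(istim)]), np.zeros(1), dt,
        np.array([params.type_code], dtype=np.int8), params.rush_larsen)
    _check_finite(S[0])
    return new


def _check_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise IntegrationFailureError(
            f"non-finite state variable {_tt06.STATE_NAMES[bad]!r}")


def run_cell(cell_type: str = "epi", duration_ms: float = 500.0,
             dt: float = 0.02, pulses: list[tuple[float, float, float]] | None = None,
             rush_larsen: bool = True,
             record_every: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one cell and return (time_ms, Vm_mV) sampled every
    ``record_every`` steps.

    ``pulses`` is a list of (onset_ms, duration_ms, amplitude_uA_per_uF)
    square current pulses; positive amplitude depolarizes.
    """
    params = CellParams(cell_type=cell_type, rush_larsen=rush_larsen)
    state = initial_state(cell_type)
    S = state.values.reshape(1, -1)
    ctypes = np.array([params.type_code], dtype=np.int8)
    pulses = pulses or []
    n_steps = int(round(duration_ms / dt))
    times, vms = [], []
    zero = np.zeros(1)
    for k in range(n_steps):
        t = k * dt
        amp = 0.0
        for (t_on, width, a) in pulses:
            if t_on <= t < t_on + width:
                amp += a
        _tt06.step_states(S, np.array([amp]), zero, dt, ctypes, rush_larsen)
        if k % record_every == 0:
            times.append(t + dt)
            vms.append(S[0, 0])
    _check_finite(S[0])
    return np.asarray(times), np.asarray(vms)


def apd90(time_ms: np.ndarray, vm_mv: np.ndarray) -> float:
    """Action-potential duration at 90% repolarization of the first AP.

    Measured from the maximum-upstroke instant to the first later crossing of
    Vm below V_peak - 0.9 * (V_peak - V_rest), with V_rest the pre-upstroke
    minimum.
    """
    dv = np.diff(vm_mv)
    k_up = int(np.argmax(dv))
    v_rest = float(vm_mv[: max(k_up, 1)].min()) if k_up > 0 else float(vm_mv[0])
    k_peak = k_up + int(np.argmax(vm_mv[k_up:]))
    v_peak = float(vm_mv[k_peak])
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.flatnonzero(vm_mv[k_peak:] <= v90)
    if below.size == 0:
        raise IntegrationFailureError("no repolarization to 90% found")
    k_repol = k_peak + int(below[0])
    return float(time_ms[k_repol] - time_ms[k_up])
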