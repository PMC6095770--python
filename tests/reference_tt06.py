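"""Independent scalar transcription of the 2006 human ventricular myocyte
model, used as the oracle for the package's cell kernel.

Written directly from the published equations as plain Python (dict state,
no vectorization, no numba) so that it shares no code with
``hearts._tt06``.  Gates use the exponential update of the published code;
everything else is forward Euler.
"""

import math

KO, CAO, NAO = 5.4, 2.0, 140.0
R, T, F = 8314.472, 310.0, 96485.3415
RTF = R * T / F

VC, VSR, VSS = 0.016404, 0.001094, 0.00005468
CAP = 0.185

P = dict(
    g_na=14.838, g_k1=5.405, g_kr=0.153, g_cal=3.98e-5,
    g_bna=0.00029, g_bca=0.000592, g_pca=0.1238, k_pca=0.0005,
    g_pk=0.0146, p_nak=2.724, km_k=1.0, km_na=40.0,
    k_naca=1000.0, km_nai=87.5, km_ca=1.38, k_sat=0.1, gamma=0.35,
    p_kna=0.03, vmaxup=0.006375, k_up=0.00025, v_rel=0.102,
    k1p=0.15, k2p=0.045, k3=0.060, k4=0.005, max_sr=2.5, min_sr=1.0,
    ec=1.5, v_leak=0.00036, v_xfer=0.0038,
    bufc=0.2, kbufc=0.001, bufsr=10.0, kbufsr=0.3, bufss=0.4, kbufss=0.00025,
)

GKS = {"endo": 0.392, "M": 0.098, "epi": 0.392}
GTO = {"endo": 0.073, "M": 0.294, "epi": 0.294}

INITIAL = dict(
    v=-86.2, m=0.0, h=0.75, j=0.75, xr1=0.0, xr2=1.0, xs=0.0, r=0.0, s=1.0,
    d=0.0, f=1.0, f2=1.0, fcass=1.0, rbar=1.0,
    cai=0.00007, casr=1.3, cass=0.00007, nai=7.67, ki=138.3,
)


def _exp(x):
    return math.exp(x)


def gate_targets(v, cass, cell_type):
    """(inf, tau) for every gate at membrane potential v."""
    g = {}
    g["m"] = (1.0 / (1.0 + _exp((-56.86 - v) / 9.03)) ** 2,
              (1.0 / (1.0 + _exp((-60.0 - v) / 5.0)))
              * (0.1 / (1.0 + _exp((v + 35.0) / 5.0))
                 + 0.1 / (1.0 + _exp((v - 50.0) / 200.0))))
    hinf = 1.0 / (1.0 + _exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah, bh = 0.0, 0.77 / (0.13 * (1.0 + _exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * _exp(0.057 * v) / (1.0 + _exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.057 * _exp(-(v + 80.0) / 6.8)
        bh = 2.7 * _exp(0.079 * v) + 3.1e5 * _exp(0.3485 * v)
        aj = ((-2.5428e4 * _exp(0.2444 * v) - 6.948e-6 * _exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + _exp(0.311 * (v + 79.23))))
        bj = (0.02424 * _exp(-0.01052 * v)
              / (1.0 + _exp(-0.1378 * (v + 40.14))))
    g["h"] = (hinf, 1.0 / (ah + bh))
    g["j"] = (hinf, 1.0 / (aj + bj))
    g["xr1"] = (1.0 / (1.0 + _exp((-26.0 - v) / 7.0)),
                (450.0 / (1.0 + _exp((-45.0 - v) / 10.0)))
                * (6.0 / (1.0 + _exp((v + 30.0) / 11.5))))
    g["xr2"] = (1.0 / (1.0 + _exp((v + 88.0) / 24.0)),
                (3.0 / (1.0 + _exp((-60.0 - v) / 20.0)))
                * (1.12 / (1.0 + _exp((v - 60.0) / 20.0))))
    g["xs"] = (1.0 / (1.0 + _exp((-5.0 - v) / 14.0)),
               (1400.0 / math.sqrt(1.0 + _exp((5.0 - v) / 6.0)))
               * (1.0 / (1.0 + _exp((v - 35.0) / 15.0))) + 80.0)
    g["r"] = (1.0 / (1.0 + _exp((20.0 - v) / 6.0)),
              9.5 * _exp(-(v + 40.0) ** 2 / 1800.0) + 0.8)
    if cell_type == "endo":
        g["s"] = (1.0 / (1.0 + _exp((v + 28.0) / 5.0)),
                  1000.0 * _exp(-(v + 67.0) ** 2 / 1000.0) + 8.0)
    else:
        g["s"] = (1.0 / (1.0 + _exp((v + 20.0) / 5.0)),
                  85.0 * _exp(-(v + 45.0) ** 2 / 320.0)
                  + 5.0 / (1.0 + _exp((v - 20.0) / 5.0)) + 3.0)
    g["d"] = (1.0 / (1.0 + _exp((-8.0 - v) / 7.5)),
              (1.4 / (1.0 + _exp((-35.0 - v) / 13.0)) + 0.25)
              * (1.4 / (1.0 + _exp((v + 5.0) / 5.0)))
              + 1.0 / (1.0 + _exp((50.0 - v) / 20.0)))
    g["f"] = (1.0 / (1.0 + _exp((v + 20.0) / 7.0)),
              1102.5 * _exp(-(v + 27.0) ** 2 / 225.0)
              + 200.0 / (1.0 + _exp((13.0 - v) / 10.0))
              + 180.0 / (1.0 + _exp((v + 30.0) / 10.0)) + 20.0)
    g["f2"] = (0.67 / (1.0 + _exp((v + 35.0) / 7.0)) + 0.33,
               562.0 * _exp(-(v + 27.0) ** 2 / 240.0)
               + 31.0 / (1.0 + _exp((25.0 - v) / 10.0))
               + 80.0 / (1.0 + _exp((v + 30.0) / 10.0)))
    g["fcass"] = (0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4,
                  80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0)
    return g


def currents(s, cell_type):
    v = s["v"]
    ena = RTF * math.log(NAO / s["nai"])
    ek = RTF * math.log(KO / s["ki"])
    eks = RTF * math.log((KO + P["p_kna"] * NAO)
                         / (s["ki"] + P["p_kna"] * s["nai"]))
    eca = 0.5 * RTF * math.log(CAO / s["cai"])

    i = {}
    i["na"] = P["g_na"] * s["m"] ** 3 * s["h"] * s["j"] * (v - ena)
    vs = v - 15.0
    if abs(vs) < 1e-9:
        i["cal"] = (P["g_cal"] * s["d"] * s["f"] * s["f2"] * s["fcass"]
                    * 2.0 * F * (0.25 * s["cass"] - CAO))
    else:
        e2 = _exp(2.0 * vs / RTF)
        i["cal"] = (P["g_cal"] * s["d"] * s["f"] * s["f2"] * s["fcass"]
                    * 4.0 * vs * F / RTF * (0.25 * s["cass"] * e2 - CAO)
                    / (e2 - 1.0))
    i["to"] = GTO[cell_type] * s["r"] * s["s"] * (v - ek)
    i["kr"] = P["g_kr"] * math.sqrt(KO / 5.4) * s["xr1"] * s["xr2"] * (v - ek)
    i["ks"] = GKS[cell_type] * s["xs"] ** 2 * (v - eks)
    a1 = 0.1 / (1.0 + _exp(0.06 * (v - ek - 200.0)))
    b1 = ((3.0 * _exp(0.0002 * (v - ek + 100.0)) + _exp(0.1 * (v - ek - 10.0)))
          / (1.0 + _exp(-0.5 * (v - ek))))
    i["k1"] = P["g_k1"] * math.sqrt(KO / 5.4) * a1 / (a1 + b1) * (v - ek)
    i["naca"] = (P["k_naca"] / ((P["km_nai"] ** 3 + NAO ** 3)
                                * (P["km_ca"] + CAO)
                                * (1.0 + P["k_sat"]
                                   * _exp((P["gamma"] - 1.0) * v / RTF)))
                 * (_exp(P["gamma"] * v / RTF) * s["nai"] ** 3 * CAO
                    - _exp((P["gamma"] - 1.0) * v / RTF) * NAO ** 3
                    * s["cai"] * 2.5))
    i["nak"] = (P["p_nak"] * KO / (KO + P["km_k"])
                * s["nai"] / (s["nai"] + P["km_na"])
                / (1.0 + 0.1245 * _exp(-0.1 * v / RTF)
                   + 0.0353 * _exp(-v / RTF)))
    i["pca"] = P["g_pca"] * s["cai"] / (s["cai"] + P["k_pca"])
    i["pk"] = P["g_pk"] * (v - ek) / (1.0 + _exp((25.0 - v) / 5.98))
    i["bna"] = P["g_bna"] * (v - ena)
    i["bca"] = P["g_bca"] * (v - eca)
    return i


def _buffered(free, total_buf, k_buf, dfree):
    """New free concentration after adding dfree under instantaneous buffering."""
    bound = total_buf * free / (free + k_buf)
    b = total_buf - bound - dfree - free + k_buf
    c = k_buf * (bound + dfree + free)
    return (math.sqrt(b * b + 4.0 * c) - b) / 2.0


def step(s, istim, dt, cell_type="epi"):
    """One integration step; positive istim (uA/uF) depolarizes."""
    v = s["v"]
    i = currents(s, cell_type)
    for name, (inf, tau) in gate_targets(v, s["cass"], cell_type).items():
        s[name] = inf - (inf - s[name]) * math.exp(-dt / tau)

    kcasr = P["max_sr"] - (P["max_sr"] - P["min_sr"]) / (
        1.0 + (P["ec"] / s["casr"]) ** 2)
    k1 = P["k1p"] / kcasr
    k2 = P["k2p"] * kcasr
    s["rbar"] += dt * (-k2 * s["cass"] * s["rbar"] + P["k4"] * (1.0 - s["rbar"]))
    o = k1 * s["cass"] ** 2 * s["rbar"] / (P["k3"] + k1 * s["cass"] ** 2)
    irel = P["v_rel"] * o * (s["casr"] - s["cass"])
    ileak = P["v_leak"] * (s["casr"] - s["cai"])
    iup = P["vmaxup"] / (1.0 + (P["k_up"] / s["cai"]) ** 2)
    ixfer = P["v_xfer"] * (s["cass"] - s["cai"])

    s["casr"] = _buffered(s["casr"], P["bufsr"], P["kbufsr"],
                          dt * (iup - irel - ileak))
    dcass = dt * (-ixfer * VC / VSS + irel * VSR / VSS
                  - i["cal"] / (2.0 * VSS * F) * CAP)
    s["cass"] = _buffered(s["cass"], P["bufss"], P["kbufss"], dcass)
    dcai = dt * (-(i["bca"] + i["pca"] - 2.0 * i["naca"]) / (2.0 * VC * F) * CAP
                 - (iup - ileak) * VSR / VC + ixfer)
    s["cai"] = _buffered(s["cai"], P["bufc"], P["kbufc"], dcai)

    s["nai"] += dt * -(i["na"] + i["bna"] + 3.0 * i["nak"]
                       + 3.0 * i["naca"]) / (VC * F) * CAP
    s["ki"] += dt * -(i["k1"] + i["to"] + i["kr"] + i["ks"] - 2.0 * i["nak"]
                      + i["pk"] - istim) / (VC * F) * CAP

    s["v"] = v + dt * (-(sum(i.values())) + istim)
    return s


def run(cell_type="epi", duration_ms=500.0, dt=0.001,
        pulses=(), record_every_ms=0.5):
    """Integrate from the published initial conditions; returns (t, Vm) lists."""
    s = dict(INITIAL)
    n = int(round(duration_ms / dt))
    rec = max(1, int(round(record_every_ms / dt)))
    ts, vs = [], []
    for k in range(n):
        t = k * dt
        amp = sum(a for (t0, w, a) in pulses if t0 <= t < t0 + w)
        step(s, amp, dt, cell_type)
        if k % rec == 0:
            ts.append(t + dt)
            vs.append(s["v"])
    return ts, vs
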