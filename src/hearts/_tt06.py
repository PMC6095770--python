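"""Numba kernels for the ten Tusscher-Panfilov 2006 human ventricular myocyte model.

The model is written in the units of the published formulation: membrane
potential in mV, time in ms, ionic concentrations in mM, current densities in
uA/uF (identically pA/pF, so the membrane capacitance cancels in dV/dt).
State layout (19 variables per cell) is given by ``STATE_NAMES``.

Sign convention: a positive external stimulus current depolarizes the cell,
i.e. dV/dt = -(sum of ionic currents) + i_stim + dv_ext, where ``dv_ext`` is
any externally supplied rate (e.g. the diffusion term of a tissue solver).
"""

import numpy as np
from numba import njit

STATE_NAMES = (
    "Vm", "m", "h", "j", "Xr1", "Xr2", "Xs", "r", "s", "d", "f", "f2",
    "fCass", "Rbar", "Cai", "CaSR", "Cass", "Nai", "Ki",
)
N_STATES = len(STATE_NAMES)

# Gate variables (dimensionless, constrained to [0, 1]).
GATE_NAMES = ("m", "h", "j", "Xr1", "Xr2", "Xs", "r", "s", "d", "f", "f2", "fCass")

# Cell type codes used in the kernels.
ENDO, MID, EPI = 0, 1, 2

# --- fixed model constants -------------------------------------------------
R_GAS = 8314.472       # mJ/(mol K)
T_KELVIN = 310.0       # K
FARADAY = 96485.3415   # C/mol
RTONF = R_GAS * T_KELVIN / FARADAY

KO = 5.4               # mM
CAO = 2.0              # mM
NAO = 140.0            # mM

VC = 0.016404          # um^3 (scaled cytoplasmic volume)
VSR = 0.001094
VSS = 0.00005468
BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025
VMAXUP, KUP = 0.006375, 0.00025
VREL = 0.102           # mM/ms
K1P, K2P, K3, K4 = 0.15, 0.045, 0.060, 0.005
MAXSR, MINSR, EC = 2.5, 1.0, 1.5
VLEAK, VXFER = 0.00036, 0.0038
CAPACITANCE = 0.185    # uF

G_NA = 14.838
G_K1 = 5.405
G_KR = 0.153
G_CAL = 0.0000398
G_BNA = 0.00029
G_BCA = 0.000592
G_PCA = 0.1238
K_PCA = 0.0005
G_PK = 0.0146
P_NAK = 2.724
KM_K, KM_NA = 1.0, 40.0
K_NACA = 1000.0
KM_NAI, KM_CA, KSAT, GAMMA = 87.5, 1.38, 0.1, 0.35
P_KNA = 0.03

# Cell-type dependent conductances, indexed by (ENDO, MID, EPI).
G_KS_BY_TYPE = (0.392, 0.098, 0.392)
G_TO_BY_TYPE = (0.073, 0.294, 0.294)

INV_VC_F = 1.0 / (VC * FARADAY)
INV_VC_F2 = 1.0 / (2.0 * VC * FARADAY)
INV_VSS_F2 = 1.0 / (2.0 * VSS * FARADAY)


@njit(cache=True, fastmath=True)
def _step_one(S, i, istim, dv_ext, dt, gks, gto, endo_s, rush_larsen):
    """Advance cell ``i`` of state array ``S`` (shape (n, 19)) by one step."""
    V = S[i, 0]
    m = S[i, 1]; h = S[i, 2]; j = S[i, 3]
    xr1 = S[i, 4]; xr2 = S[i, 5]; xs = S[i, 6]
    r = S[i, 7]; s = S[i, 8]
    d = S[i, 9]; f = S[i, 10]; f2 = S[i, 11]; fcass = S[i, 12]
    rbar = S[i, 13]
    cai = S[i, 14]; casr = S[i, 15]; cass = S[i, 16]
    nai = S[i, 17]; ki = S[i, 18]

    ena = RTONF * np.log(NAO / nai)
    ek = RTONF * np.log(KO / ki)
    eks = RTONF * np.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
    eca = 0.5 * RTONF * np.log(CAO / cai)

    # --- membrane currents (uA/uF) ---
    ina = G_NA * m * m * m * h * j * (V - ena)

    vshift = V - 15.0
    expv = np.exp(2.0 * vshift / RTONF)
    if abs(vshift) < 1e-6:
        # limit of the GHK-type driving term at V = 15 mV
        ical = G_CAL * d * f * f2 * fcass * 2.0 * FARADAY * (0.25 * cass - CAO)
    else:
        ical = (G_CAL * d * f * f2 * fcass * 4.0 * vshift * FARADAY / RTONF
                * (0.25 * cass * expv - CAO) / (expv - 1.0))

    ito = gto * r * s * (V - ek)
    ikr = G_KR * np.sqrt(KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = gks * xs * xs * (V - eks)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0))
           + np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = G_K1 * np.sqrt(KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)

    inaca = (K_NACA * (1.0 / (KM_NAI ** 3 + NAO ** 3)) * (1.0 / (KM_CA + CAO))
             * (1.0 / (1.0 + KSAT * np.exp((GAMMA - 1.0) * V / RTONF)))
             * (np.exp(GAMMA * V / RTONF) * nai ** 3 * CAO
                - np.exp((GAMMA - 1.0) * V / RTONF) * NAO ** 3 * cai * 2.5))

    inak = (P_NAK * (KO / (KO + KM_K)) * (nai / (nai + KM_NA))
            / (1.0 + 0.1245 * np.exp(-0.1 * V / RTONF)
               + 0.0353 * np.exp(-V / RTONF)))

    ipca = G_PCA * cai / (cai + K_PCA)
    ipk = G_PK * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = G_BNA * (V - ena)
    ibca = G_BCA * (V - eca)

    iion = (ikr + iks + ik1 + ito + ina + ibna + ical + ibca + inak
            + inaca + ipca + ipk)

    # --- gate rates ---
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8

    if endo_s:
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = 85.0 * np.exp(-(V + 45.0) ** 2 / 320.0) \
            + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)

    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))

    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    if rush_larsen:
        m = m_inf - (m_inf - m) * np.exp(-dt / tau_m)
        h = h_inf - (h_inf - h) * np.exp(-dt / tau_h)
        j = j_inf - (j_inf - j) * np.exp(-dt / tau_j)
        xr1 = xr1_inf - (xr1_inf - xr1) * np.exp(-dt / tau_xr1)
        xr2 = xr2_inf - (xr2_inf - xr2) * np.exp(-dt / tau_xr2)
        xs = xs_inf - (xs_inf - xs) * np.exp(-dt / tau_xs)
        r = r_inf - (r_inf - r) * np.exp(-dt / tau_r)
        s = s_inf - (s_inf - s) * np.exp(-dt / tau_s)
        d = d_inf - (d_inf - d) * np.exp(-dt / tau_d)
        f = f_inf - (f_inf - f) * np.exp(-dt / tau_f)
        f2 = f2_inf - (f2_inf - f2) * np.exp(-dt / tau_f2)
        fcass = fcass_inf - (fcass_inf - fcass) * np.exp(-dt / tau_fcass)
    else:
        m += dt * (m_inf - m) / tau_m
        h += dt * (h_inf - h) / tau_h
        j += dt * (j_inf - j) / tau_j
        xr1 += dt * (xr1_inf - xr1) / tau_xr1
        xr2 += dt * (xr2_inf - xr2) / tau_xr2
        xs += dt * (xs_inf - xs) / tau_xs
        r += dt * (r_inf - r) / tau_r
        s += dt * (s_inf - s) / tau_s
        d += dt * (d_inf - d) / tau_d
        f += dt * (f_inf - f) / tau_f
        f2 += dt * (f2_inf - f2) / tau_f2
        fcass += dt * (fcass_inf - fcass) / tau_fcass

    # --- calcium subsystem ---
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    rbar += dt * (-k2 * cass * rbar + K4 * (1.0 - rbar))
    o_rel = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
    irel = VREL * o_rel * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    # SR calcium, with instantaneous-buffer correction
    casrbuf = BUFSR * casr / (casr + KBUFSR)
    dcasr = dt * (iup - irel - ileak)
    bjsr = BUFSR - casrbuf - dcasr - casr + KBUFSR
    cjsr = KBUFSR * (casrbuf + dcasr + casr)
    casr = (np.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    cassbuf = BUFSS * cass / (cass + KBUFSS)
    dcass = dt * (-ixfer * (VC / VSS) + irel * (VSR / VSS)
                  + (-ical * INV_VSS_F2 * CAPACITANCE))
    bcss = BUFSS - cassbuf - dcass - cass + KBUFSS
    ccss = KBUFSS * (cassbuf + dcass + cass)
    cass = (np.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

    caibuf = BUFC * cai / (cai + KBUFC)
    dcai = dt * ((-(ibca + ipca - 2.0 * inaca) * INV_VC_F2 * CAPACITANCE)
                 - (iup - ileak) * (VSR / VC) + ixfer)
    bc = BUFC - caibuf - dcai - cai + KBUFC
    cc = KBUFC * (caibuf + dcai + cai)
    cai = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    nai += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)) * INV_VC_F * CAPACITANCE
    ki += dt * (-(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim)) \
        * INV_VC_F * CAPACITANCE

    V += dt * (-iion + istim + dv_ext)

    S[i, 0] = V
    S[i, 1] = m; S[i, 2] = h; S[i, 3] = j
    S[i, 4] = xr1; S[i, 5] = xr2; S[i, 6] = xs
    S[i, 7] = r; S[i, 8] = s
    S[i, 9] = d; S[i, 10] = f; S[i, 11] = f2; S[i, 12] = fcass
    S[i, 13] = rbar
    S[i, 14] = cai; S[i, 15] = casr; S[i, 16] = cass
    S[i, 17] = nai; S[i, 18] = ki


@njit(cache=True, fastmath=True)
def step_states(S, istim, dv_ext, dt, cell_types, rush_larsen):
    """Advance every cell in ``S`` (shape (n, 19)) by one time step of ``dt`` ms.

    ``istim`` and ``dv_ext`` are per-cell rates in mV/ms (uA/uF); ``cell_types``
    holds the 0/1/2 (endo/mid/epi) code per cell.
    """
    n = S.shape[0]
    for i in range(n):
        ct = cell_types[i]
        gks = G_KS_BY_TYPE[2] if ct == 2 else (
            G_KS_BY_TYPE[1] if ct == 1 else G_KS_BY_TYPE[0])
        gto = G_TO_BY_TYPE[2] if ct == 2 else (
            G_TO_BY_TYPE[1] if ct == 1 else G_TO_BY_TYPE[0])
        endo_s = ct == 0
        _step_one(S, i, istim[i], dv_ext[i], dt, gks, gto, endo_s, rush_larsen)
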