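"""Compiled (numba) kernels for the stochastic lattice model.

Everything here mirrors the pure-python reference implementations in
:mod:`coopgate.ltcc` and :mod:`coopgate.cru`; the rate mathematics is kept
in one device function per model so the two code paths can be cross-checked
(see ``tests/test_kernels.py``).  Parameters are passed as one flat float64
array addressed by the ``P_*`` index constants below.

State encodings
---------------
LTCC: 0 C2, 1 C1, 2 O, 3 I1Ca, 4 I2Ca, 5 I1Ba, 6 I2Ba (as in ``ltcc``).
RyR : counts per CRU in 4 states: 0 C (closed), 1 O (open, conducting),
      2 OI (open-inactivated, non-conducting), 3 CI (closed-inactivated).
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter-vector layout
# ---------------------------------------------------------------------------
(P_TAU_PO, P_R1, P_R2, P_S1BAR, P_S1P, P_K1BAR, P_K1P, P_K2, P_K2P,
 P_CPTILDE, P_CPMINUS, P_TCAMAX, P_TBA,
 P_W1, P_W2, P_POX, P_CPX,
 P_PCA, P_GAMI, P_GAMO, P_CAO, P_RTF,
 P_RYR_NU, P_RYR_KA, P_RYR_KJ, P_RYR_HILL, P_RYR_KOC, P_RYR_KICP, P_RYR_KIO, P_RYR_GREL,
 P_VI, P_VS, P_VP, P_VNSR, P_VJSR,
 P_TAUP, P_TAUSI, P_TAUTR,
 P_TAU_CI_L, P_TAU_CI_T, P_TAU_CS_L, P_TAU_CS_T, P_TAU_NSR_L, P_TAU_NSR_T,
 P_VUP, P_KUP, P_VNCX, P_KSAT, P_ETA, P_KMNA, P_KMCA, P_NAI, P_NAO,
 P_GCABK, P_VSLCAP, P_KSLCAP,
 P_BCAM, P_KCAM, P_BSR, P_KSR, P_BCSQN, P_KCSQN, P_BT, P_KONT, P_KOFFT,
 P_CM_CRU, P_GNA, P_GK1, P_GKR, P_GKS, P_GTO, P_GKP, P_ENA, P_EK,
 P_PA2UM,
 N_PARAMS) = range(76)


def params_array(lp, **overrides) -> np.ndarray:
    """Build the kernel parameter vector from an ``LtccParams`` plus the
    module-level CRU/membrane constants; keyword overrides use the P_* names
    in lower case without the prefix (e.g. ``vncx=10.0``)."""
    from . import constants as K

    P = np.zeros(N_PARAMS)
    P[P_TAU_PO], P[P_R1], P[P_R2] = lp.tau_po, lp.r1, lp.r2
    P[P_S1BAR], P[P_S1P], P[P_K1BAR], P[P_K1P] = lp.s1_bar, lp.s1p, lp.k1_bar, lp.k1p
    P[P_K2], P[P_K2P] = lp.k2, lp.k2p
    P[P_CPTILDE], P[P_CPMINUS], P[P_TCAMAX], P[P_TBA] = (
        lp.cp_tilde, lp.cp_minus, lp.t_ca_max, lp.t_ba)
    P[P_W1], P[P_W2], P[P_POX], P[P_CPX] = lp.w1, lp.w2, lp.po_x, lp.cp_x
    P[P_PCA], P[P_GAMI], P[P_GAMO], P[P_CAO], P[P_RTF] = (
        lp.p_ca, lp.gamma_i, lp.gamma_o, lp.ca_o, lp.rt_f)
    P[P_RYR_NU], P[P_RYR_KA] = K.RYR_NU, K.RYR_KA
    P[P_RYR_KJ], P[P_RYR_HILL] = K.RYR_KJ, K.RYR_HILL
    P[P_RYR_KOC], P[P_RYR_KICP], P[P_RYR_KIO], P[P_RYR_GREL] = (
        K.RYR_K_OC, K.RYR_KI_CP, K.RYR_K_IO, K.RYR_G_REL)
    P[P_VI], P[P_VS], P[P_VP], P[P_VNSR], P[P_VJSR] = K.V_I, K.V_S, K.V_P, K.V_NSR, K.V_JSR
    P[P_TAUP], P[P_TAUSI], P[P_TAUTR] = K.TAU_P, K.TAU_SI, K.TAU_TR
    P[P_TAU_CI_L], P[P_TAU_CI_T] = K.TAU_CI_L, K.TAU_CI_T
    P[P_TAU_CS_L], P[P_TAU_CS_T] = K.TAU_CS_L, K.TAU_CS_T
    P[P_TAU_NSR_L], P[P_TAU_NSR_T] = K.TAU_NSR_L, K.TAU_NSR_T
    P[P_VUP], P[P_KUP], P[P_VNCX] = K.VUP, K.KUP, K.V_NCX
    P[P_KSAT], P[P_ETA], P[P_KMNA], P[P_KMCA] = K.NCX_KSAT, K.NCX_ETA, K.NCX_KMNA, K.NCX_KMCA
    P[P_NAI], P[P_NAO] = K.NA_I, K.NA_O
    P[P_GCABK], P[P_VSLCAP], P[P_KSLCAP] = K.G_CABK, K.V_SLCAP, K.K_SLCAP
    P[P_BCAM], P[P_KCAM], P[P_BSR], P[P_KSR] = K.BUF_CAM_B, K.BUF_CAM_K, K.BUF_SR_B, K.BUF_SR_K
    P[P_BCSQN], P[P_KCSQN] = K.BUF_CSQN_B, K.BUF_CSQN_K
    P[P_BT], P[P_KONT], P[P_KOFFT] = K.TRPN_B, K.TRPN_KON, K.TRPN_KOFF
    P[P_CM_CRU] = K.CM_PER_CRU
    P[P_GNA], P[P_GK1], P[P_GKR], P[P_GKS], P[P_GTO], P[P_GKP] = (
        K.G_NA, K.G_K1, K.G_KR, K.G_KS, K.G_TO, K.G_KP)
    P[P_ENA], P[P_EK] = K.E_NA, K.E_K
    P[P_PA2UM] = K.PA_TO_UMMS
    name_map = {n[2:].lower(): i for n, i in globals().items()
                if n.startswith("P_") and isinstance(i, int)}
    for k, v in overrides.items():
        P[name_map[k]] = float(v)
    return P


@njit(cache=True, inline="always")
def _sig(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def ltcc_rate_vector(V, cp, n_open, P, out):
    """Fill ``out`` (length 20) with the transition rates, in the order
    alpha, beta, r1, r2, s1, s2, s1p, s2p, k1, k2, k3, k4, k5, k6,
    k1p, k2p, k3p, k4p, k5p, k6p (gamma factors included)."""
    s = _sig(15.0 * (n_open / 3.0 - P[P_POX])) * _sig(cp - P[P_CPX])
    g1 = 1.0 + P[P_W1] * s
    g2 = 1.0 + P[P_W2] * s
    po_inf = _sig(V / 8.0)
    alpha = po_inf / P[P_TAU_PO] * g1
    beta = (1.0 - po_inf) / P[P_TAU_PO]
    if cp > 0.0:
        f_cp = 1.0 / (1.0 + (P[P_CPTILDE] / cp) ** 3)
    else:
        f_cp = 0.0
    s1 = P[P_S1BAR] * f_cp
    k1 = P[P_K1BAR] * f_cp
    r1 = P[P_R1] * g2
    s2 = (P[P_S1BAR] / P[P_K1BAR]) * P[P_K2] * P[P_R2] / P[P_R1]
    s2p = P[P_S1P] * (P[P_K2P] / P[P_K1P]) * P[P_R2] / P[P_R1]
    k3 = 1.0 / (3.0 * (1.0 + math.exp((V + 40.0) / 3.0)))
    r_v = 10.0 + 4954.0 * math.exp(V / 15.6)
    t_ca = P[P_TCAMAX] / (1.0 + (cp / P[P_CPMINUS]) ** 4)
    p_r = _sig(-(V + 40.0) / 4.0)
    p_s = _sig((V + 40.0) / 11.32)
    tau_ca = (r_v - t_ca) * p_r + t_ca
    tau_ba = (r_v - P[P_TBA]) * p_r + P[P_TBA]
    k5 = (1.0 - p_s) / tau_ca
    k6 = f_cp * p_s / tau_ca
    k5p = (1.0 - p_s) / tau_ba
    k6p = p_s / tau_ba
    ab = math.exp(V / 8.0)
    k4 = k3 * ab * (P[P_K1BAR] / P[P_K2]) * (1.0 - p_s) / p_s
    k4p = k3 * ab * (P[P_K1P] / P[P_K2P]) * k5p / k6p
    out[0] = alpha; out[1] = beta; out[2] = r1; out[3] = P[P_R2]
    out[4] = s1; out[5] = s2; out[6] = P[P_S1P]; out[7] = s2p
    out[8] = k1; out[9] = P[P_K2]; out[10] = k3; out[11] = k4
    out[12] = k5; out[13] = k6
    out[14] = P[P_K1P]; out[15] = P[P_K2P]; out[16] = k3; out[17] = k4p
    out[18] = k5p; out[19] = k6p


@njit(cache=True, inline="always")
def _fill_exit_table(r, cum, tgt, nex):
    """Cumulative exit-rate table (7 states x up to 4 exits) from a rate
    vector in the ``ltcc_rate_vector`` order."""
    # C2: -> C1 (alpha), -> I2Ca (k6), -> I2Ba (k6p)
    cum[0, 0] = r[0]; tgt[0, 0] = 1
    cum[0, 1] = cum[0, 0] + r[13]; tgt[0, 1] = 4
    cum[0, 2] = cum[0, 1] + r[19]; tgt[0, 2] = 6
    nex[0] = 3
    # C1: -> C2 (beta), -> O (r1), -> I1Ca (k1), -> I1Ba (k1p)
    cum[1, 0] = r[1]; tgt[1, 0] = 0
    cum[1, 1] = cum[1, 0] + r[2]; tgt[1, 1] = 2
    cum[1, 2] = cum[1, 1] + r[8]; tgt[1, 2] = 3
    cum[1, 3] = cum[1, 2] + r[14]; tgt[1, 3] = 5
    nex[1] = 4
    # O: -> C1 (r2), -> I1Ca (s1), -> I1Ba (s1p)
    cum[2, 0] = r[3]; tgt[2, 0] = 1
    cum[2, 1] = cum[2, 0] + r[4]; tgt[2, 1] = 3
    cum[2, 2] = cum[2, 1] + r[6]; tgt[2, 2] = 5
    nex[2] = 3
    # I1Ca: -> O (s2), -> C1 (k2), -> I2Ca (k3)
    cum[3, 0] = r[5]; tgt[3, 0] = 2
    cum[3, 1] = cum[3, 0] + r[9]; tgt[3, 1] = 1
    cum[3, 2] = cum[3, 1] + r[10]; tgt[3, 2] = 4
    nex[3] = 3
    # I2Ca: -> I1Ca (k4), -> C2 (k5)
    cum[4, 0] = r[11]; tgt[4, 0] = 3
    cum[4, 1] = cum[4, 0] + r[12]; tgt[4, 1] = 0
    nex[4] = 2
    # I1Ba: -> O (s2p), -> C1 (k2p), -> I2Ba (k3p)
    cum[5, 0] = r[7]; tgt[5, 0] = 2
    cum[5, 1] = cum[5, 0] + r[15]; tgt[5, 1] = 1
    cum[5, 2] = cum[5, 1] + r[16]; tgt[5, 2] = 6
    nex[5] = 3
    # I2Ba: -> I1Ba (k4p), -> C2 (k5p)
    cum[6, 0] = r[17]; tgt[6, 0] = 5
    cum[6, 1] = cum[6, 0] + r[18]; tgt[6, 1] = 0
    nex[6] = 2


@njit(cache=True)
def run_cluster_clamped(size, V, cp, n_steps, dt, seed, P):
    """Simulate one LTCC cluster under clamped (V, c_p).

    Returns the per-step open count (int16, length n_steps+1).  The update
    rule matches ``ltcc.advance_cluster``: rates frozen at the start-of-step
    open count, at most one transition per channel per step.
    """
    np.random.seed(seed)
    states = np.zeros(size, dtype=np.int8)  # all C2
    trace = np.zeros(n_steps + 1, dtype=np.int16)
    r = np.zeros(20)
    cum = np.zeros((7, 4))
    tgt = np.zeros((7, 4), dtype=np.int8)
    nex = np.zeros(7, dtype=np.int8)
    n_open = 0
    for step in range(1, n_steps + 1):
        ltcc_rate_vector(V, cp, n_open, P, r)
        _fill_exit_table(r, cum, tgt, nex)
        for i in range(size):
            s = states[i]
            x = np.random.random() / dt
            ne = nex[s]
            if x < cum[s, ne - 1]:
                for k in range(ne):
                    if x < cum[s, k]:
                        states[i] = tgt[s, k]
                        break
        n_open = 0
        for i in range(size):
            if states[i] == 2:
                n_open += 1
        trace[step] = n_open
    return trace


@njit(cache=True, inline="always")
def _ghk_current(V, cp, P):
    z = V / P[P_RTF]
    a = 0.001 * P[P_GAMI] * cp
    b = P[P_GAMO] * P[P_CAO]
    if abs(z) < 1.0e-7:
        return 2.0 * P[P_PCA] * 96.485 * (a - b)
    e2z = math.exp(2.0 * z)
    return 4.0 * P[P_PCA] * z * 96.485 * (a * e2z - b) / (e2z - 1.0)


@njit(cache=True, inline="always")
def _ncx_flux(V, cs, P):
    """NCX Ca flux on c_s (uM/ms); negative = extrusion."""
    a = V / P[P_RTF]
    cs_mm = cs * 1.0e-3
    e1 = math.exp(P[P_ETA] * a)
    e2 = math.exp((P[P_ETA] - 1.0) * a)
    num = e1 * P[P_NAI] ** 3 * P[P_CAO] - e2 * P[P_NAO] ** 3 * cs_mm
    den = ((P[P_KMNA] ** 3 + P[P_NAO] ** 3) * (P[P_KMCA] + P[P_CAO])
           * (1.0 + P[P_KSAT] * e2))
    return P[P_VNCX] * num / den


@njit(cache=True, inline="always")
def _beta_inst(c, B1, K1, B2, K2):
    return 1.0 / (1.0 + B1 * K1 / (K1 + c) ** 2 + B2 * K2 / (K2 + c) ** 2)


@njit(cache=True, inline="always")
def _binom(n, p):
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    return np.random.binomial(n, p)


@njit(cache=True)
def _ryr_step(ryr, cp, cjsr, dt, P):
    """Advance the 4-state RyR counts of one CRU by dt (binomial draws)."""
    psi = cjsr ** P[P_RYR_HILL] / (cjsr ** P[P_RYR_HILL] + P[P_RYR_KJ] ** P[P_RYR_HILL])
    cp4 = cp ** 4
    k_co = P[P_RYR_NU] * cp4 / (cp4 + P[P_RYR_KA] ** 4) * psi
    k_oc = P[P_RYR_KOC]
    k_in = P[P_RYR_KICP] * cp
    k_re = P[P_RYR_KIO]
    # C -> O / C -> CI
    tot = k_co + k_in
    if tot > 0.0 and ryr[0] > 0:
        leave = _binom(ryr[0], 1.0 - math.exp(-tot * dt))
        to_o = _binom(leave, k_co / tot)
        ryr[0] -= leave
        ryr[1] += to_o
        ryr[3] += leave - to_o
    # O -> C / O -> OI
    tot = k_oc + k_in
    if ryr[1] > 0:
        leave = _binom(ryr[1], 1.0 - math.exp(-tot * dt))
        to_c = _binom(leave, k_oc / tot)
        ryr[1] -= leave
        ryr[0] += to_c
        ryr[2] += leave - to_c
    # OI -> CI / OI -> O
    tot = k_oc + k_re
    if ryr[2] > 0:
        leave = _binom(ryr[2], 1.0 - math.exp(-tot * dt))
        to_ci = _binom(leave, k_oc / tot)
        ryr[2] -= leave
        ryr[3] += to_ci
        ryr[1] += leave - to_ci
    # CI -> C / CI -> OI
    tot = k_re + k_co
    if ryr[3] > 0:
        leave = _binom(ryr[3], 1.0 - math.exp(-tot * dt))
        to_c = _binom(leave, k_re / tot)
        ryr[3] -= leave
        ryr[0] += to_c
        ryr[2] += leave - to_c


# membrane gate indices in the mem vector
M_V, M_M, M_H, M_J, M_XR, M_XS, M_ATO, M_ITO = range(8)


@njit(cache=True)
def _gate_rates(V, rates):
    """Luo-Rudy-type HH rate functions for the sarcolemmal Na/K currents.

    ``rates``: [am, bm, ah, bh, aj, bj, xr_inf, tau_xr, xs_inf, tau_xs,
                a_inf, tau_a, i_inf, tau_i]."""
    dv = V + 47.13
    if abs(dv) < 1.0e-6:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-V / 11.0)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * math.exp(-(80.0 + V) / 6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        aj = ((-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    rates[0] = am; rates[1] = bm; rates[2] = ah; rates[3] = bh
    rates[4] = aj; rates[5] = bj
    rates[6] = _sig((V + 21.5) / 7.5)
    rates[7] = 30.0 + 250.0 / (1.0 + math.exp((V + 20.0) / 15.0))
    rates[8] = _sig((V - 1.5) / 16.7)
    rates[9] = 50.0 + 350.0 / (1.0 + math.exp((V - 10.0) / 20.0))
    rates[10] = _sig((V + 10.0) / 11.0)
    rates[11] = 2.0
    rates[12] = _sig(-(V + 45.0) / 5.0)
    rates[13] = 25.0 + 30.0 / (1.0 + math.exp((V + 60.0) / -10.0))


@njit(cache=True, inline="always")
def _k_currents(V, mem, P):
    """Sum of the K+ currents and I_Na (A/F) at the present gate values."""
    ek = P[P_EK]
    i_na = P[P_GNA] * mem[M_M] ** 3 * mem[M_H] * mem[M_J] * (V - P[P_ENA])
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (V - ek - 59.215)))
    bk1 = ((0.49124 * math.exp(0.08032 * (V - ek + 5.476))
            + math.exp(0.06175 * (V - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (V - ek + 4.753))))
    i_k1 = P[P_GK1] * ak1 / (ak1 + bk1) * (V - ek)
    rect = 1.0 / (1.0 + math.exp((V + 9.0) / 22.4))
    i_kr = P[P_GKR] * mem[M_XR] * rect * (V - ek)
    i_ks = P[P_GKS] * mem[M_XS] * mem[M_XS] * (V - ek)
    i_to = P[P_GTO] * mem[M_ATO] * mem[M_ITO] * (V - ek)
    i_kp = P[P_GKP] * (V - ek) / (1.0 + math.exp((7.488 - V) / 5.98))
    return i_na + i_k1 + i_kr + i_ks + i_to + i_kp


@njit(cache=True)
def run_lattice(mode, v_cmd, istim, n_steps, dt, stride,
                nx, ny, nz, chan_state, chan_off,
                ryr, ci, cs, cp, cnsr, cjsr, bti, bts, mem,
                P, seed, clamp_channels,
                out_v, out_ical, out_incx, out_ci, out_cs, out_cjsr,
                out_nopen, out_cp):
    """Advance the full CRU lattice over ``n_steps`` steps of ``dt`` ms.

    mode 0: V follows ``v_cmd`` (voltage/AP clamp); membrane gates are not
    integrated.  mode 1: paced free-running membrane, ``istim`` is the
    stimulus current (A/F) per step.  All state arrays are updated in place;
    the ``out_*`` arrays (length ceil(n_steps/stride)) receive whole-cell
    traces.  ``clamp_channels`` freezes RyR and LTCC states (deterministic
    limit used by tests).  Returns the number of negativity clamps applied
    (0 in a well-resolved run).
    """
    np.random.seed(seed)
    n = nx * ny * nz
    n_clamped = 0
    r = np.zeros(20)
    cum = np.zeros((7, 4))
    tgt = np.zeros((7, 4), dtype=np.int8)
    nex = np.zeros(7, dtype=np.int8)
    grates = np.zeros(14)
    ci_old = np.zeros(n)
    cs_old = np.zeros(n)
    cnsr_old = np.zeros(n)
    n_open = np.zeros(n, dtype=np.int16)
    for q in range(n):
        c = 0
        for ii in range(chan_off[q], chan_off[q + 1]):
            if chan_state[ii] == 2:
                c += 1
        n_open[q] = c

    inv_tau_ci_l = 1.0 / P[P_TAU_CI_L]
    inv_tau_ci_t = 1.0 / P[P_TAU_CI_T]
    inv_tau_cs_l = 1.0 / P[P_TAU_CS_L]
    inv_tau_cs_t = 1.0 / P[P_TAU_CS_T]
    inv_tau_nsr_l = 1.0 / P[P_TAU_NSR_L]
    inv_tau_nsr_t = 1.0 / P[P_TAU_NSR_T]
    vs_vi = P[P_VS] / P[P_VI]
    vp_vs = P[P_VP] / P[P_VS]
    vi_vnsr = P[P_VI] / P[P_VNSR]
    vjsr_vnsr = P[P_VJSR] / P[P_VNSR]
    vp_vjsr = P[P_VP] / P[P_VJSR]
    cm_total = n * P[P_CM_CRU]

    for step in range(n_steps):
        if mode == 0:
            V = v_cmd[step]
        else:
            V = mem[M_V]
        for q in range(n):
            ci_old[q] = ci[q]
            cs_old[q] = cs[q]
            cnsr_old[q] = cnsr[q]
        ical_pa = 0.0
        incx_pa = 0.0

        for q in range(n):
            # --- LTCC cluster -------------------------------------------
            cpq = cp[q]
            ltcc_rate_vector(V, cpq, n_open[q], P, r)
            no = 0
            if not clamp_channels:
                _fill_exit_table(r, cum, tgt, nex)
                for ii in range(chan_off[q], chan_off[q + 1]):
                    s = chan_state[ii]
                    x = np.random.random() / dt
                    ne = nex[s]
                    if x < cum[s, ne - 1]:
                        for k in range(ne):
                            if x < cum[s, k]:
                                chan_state[ii] = tgt[s, k]
                                break
                    if chan_state[ii] == 2:
                        no += 1
                n_open[q] = no
            else:
                no = n_open[q]
            i_ca = _ghk_current(V, cpq, P)
            ical_pa += i_ca * no
            j_cal = -P[P_PA2UM] * i_ca * no / P[P_VP]  # influx > 0, uM/ms in cleft

            # --- RyR cluster --------------------------------------------
            if not clamp_channels:
                _ryr_step(ryr[q], cpq, cjsr[q], dt, P)
            n_ryr_open = ryr[q, 1]
            j_rel = P[P_RYR_GREL] * n_ryr_open * (cjsr[q] - cpq)

            # --- local fluxes -------------------------------------------
            i_dsi = (cs_old[q] - ci_old[q]) / P[P_TAUSI]
            i_tr = (cnsr_old[q] - cjsr[q]) / P[P_TAUTR]
            i_up = P[P_VUP] * ci_old[q] ** 2 / (ci_old[q] ** 2 + P[P_KUP] ** 2)
            j_ncx = _ncx_flux(V, cs_old[q], P)
            incx_pa += 0.0965 * P[P_VS] * j_ncx
            j_bk = P[P_GCABK]
            j_slcap = P[P_VSLCAP] * cs_old[q] / (cs_old[q] + P[P_KSLCAP])
            i_tci = P[P_KONT] * ci_old[q] * (P[P_BT] - bti[q]) - P[P_KOFFT] * bti[q]
            i_tcs = P[P_KONT] * cs_old[q] * (P[P_BT] - bts[q]) - P[P_KOFFT] * bts[q]

            # --- nearest-neighbour diffusion (no-flux faces) ------------
            x = q // (ny * nz)
            rem = q - x * ny * nz
            y = rem // nz
            z = rem - y * nz
            i_ci = 0.0
            i_cs = 0.0
            i_nsr = 0.0
            if x > 0:
                i_ci += (ci_old[q - ny * nz] - ci_old[q]) * inv_tau_ci_l
                i_cs += (cs_old[q - ny * nz] - cs_old[q]) * inv_tau_cs_l
                i_nsr += (cnsr_old[q - ny * nz] - cnsr_old[q]) * inv_tau_nsr_l
            if x < nx - 1:
                i_ci += (ci_old[q + ny * nz] - ci_old[q]) * inv_tau_ci_l
                i_cs += (cs_old[q + ny * nz] - cs_old[q]) * inv_tau_cs_l
                i_nsr += (cnsr_old[q + ny * nz] - cnsr_old[q]) * inv_tau_nsr_l
            if y > 0:
                i_ci += (ci_old[q - nz] - ci_old[q]) * inv_tau_ci_t
                i_cs += (cs_old[q - nz] - cs_old[q]) * inv_tau_cs_t
                i_nsr += (cnsr_old[q - nz] - cnsr_old[q]) * inv_tau_nsr_t
            if y < ny - 1:
                i_ci += (ci_old[q + nz] - ci_old[q]) * inv_tau_ci_t
                i_cs += (cs_old[q + nz] - cs_old[q]) * inv_tau_cs_t
                i_nsr += (cnsr_old[q + nz] - cnsr_old[q]) * inv_tau_nsr_t
            if z > 0:
                i_ci += (ci_old[q - 1] - ci_old[q]) * inv_tau_ci_t
                i_cs += (cs_old[q - 1] - cs_old[q]) * inv_tau_cs_t
                i_nsr += (cnsr_old[q - 1] - cnsr_old[q]) * inv_tau_nsr_t
            if z < nz - 1:
                i_ci += (ci_old[q + 1] - ci_old[q]) * inv_tau_ci_t
                i_cs += (cs_old[q + 1] - cs_old[q]) * inv_tau_cs_t
                i_nsr += (cnsr_old[q + 1] - cnsr_old[q]) * inv_tau_nsr_t

            # --- buffering factors --------------------------------------
            b_i = _beta_inst(ci_old[q], P[P_BCAM], P[P_KCAM], P[P_BSR], P[P_KSR])
            b_s = _beta_inst(cs_old[q], P[P_BCAM], P[P_KCAM], P[P_BSR], P[P_KSR])
            cj = cjsr[q]
            b_jsr = 1.0 / (1.0 + P[P_BCSQN] * P[P_KCSQN] / (P[P_KCSQN] + cj) ** 2)

            # --- concentration updates ----------------------------------
            ci[q] = ci_old[q] + dt * b_i * (i_dsi * vs_vi - i_up - i_tci + i_ci)
            cs[q] = (cs_old[q] + dt * b_s * (((cpq - cs_old[q]) / P[P_TAUP]) * vp_vs
                     + j_ncx - i_dsi - i_tcs + i_cs + j_bk - j_slcap))
            # cleft: exponential update toward its quasi-steady value
            src = j_rel + j_cal
            cp_inf = cs_old[q] + src * P[P_TAUP]
            cp[q] = cp_inf + (cpq - cp_inf) * math.exp(-dt / P[P_TAUP])
            cnsr[q] = cnsr_old[q] + dt * (i_up * vi_vnsr - i_tr * vjsr_vnsr + i_nsr)
            cjsr[q] = cj + dt * b_jsr * (i_tr - j_rel * vp_vjsr)
            bti[q] += dt * i_tci
            bts[q] += dt * i_tcs
            if ci[q] < 0.0:
                ci[q] = 0.0; n_clamped += 1
            if cs[q] < 0.0:
                cs[q] = 0.0; n_clamped += 1
            if cp[q] < 0.0:
                cp[q] = 0.0; n_clamped += 1
            if cjsr[q] < 0.0:
                cjsr[q] = 0.0; n_clamped += 1

        ical_af = ical_pa / cm_total
        incx_af = incx_pa / cm_total

        # --- membrane ---------------------------------------------------
        if mode == 1:
            _gate_rates(V, grates)
            i_ion = _k_currents(V, mem, P) + ical_af + incx_af
            mem[M_V] = V + dt * (-(i_ion + istim[step]))
            # Rush-Larsen gate updates
            am, bm = grates[0], grates[1]
            minf = am / (am + bm)
            mem[M_M] = minf + (mem[M_M] - minf) * math.exp(-dt * (am + bm))
            ah, bh = grates[2], grates[3]
            if ah + bh > 0:
                hinf = ah / (ah + bh)
                mem[M_H] = hinf + (mem[M_H] - hinf) * math.exp(-dt * (ah + bh))
            aj, bj = grates[4], grates[5]
            if aj + bj > 0:
                jinf = aj / (aj + bj)
                mem[M_J] = jinf + (mem[M_J] - jinf) * math.exp(-dt * (aj + bj))
            mem[M_XR] = grates[6] + (mem[M_XR] - grates[6]) * math.exp(-dt / grates[7])
            mem[M_XS] = grates[8] + (mem[M_XS] - grates[8]) * math.exp(-dt / grates[9])
            mem[M_ATO] = grates[10] + (mem[M_ATO] - grates[10]) * math.exp(-dt / grates[11])
            mem[M_ITO] = grates[12] + (mem[M_ITO] - grates[12]) * math.exp(-dt / grates[13])
        else:
            mem[M_V] = V

        if step % stride == 0:
            k = step // stride
            out_v[k] = mem[M_V] if mode == 1 else V
            out_ical[k] = ical_af
            out_incx[k] = incx_af
            s_ci = 0.0
            s_cs = 0.0
            s_cj = 0.0
            s_cp = 0.0
            s_no = 0.0
            for q in range(n):
                s_ci += ci[q]; s_cs += cs[q]; s_cj += cjsr[q]
                s_cp += cp[q]; s_no += n_open[q]
            out_ci[k] = s_ci / n
            out_cs[k] = s_cs / n
            out_cjsr[k] = s_cj / n
            out_cp[k] = s_cp / n
            out_nopen[k] = s_no / n
    return n_clamped


@njit(cache=True)
def run_single_cru(v_wave, cp_clamp, cp_wave, n_steps, dt, seed,
                   chan_state, ryr, conc, bti_bts, P,
                   out_cp, out_cjsr, out_nryr, out_nltcc):
    """One CRU with no neighbours; optionally clamp c_p to ``cp_wave``.

    ``conc`` = [ci, cs, cp, cnsr, cjsr] updated in place; used for spark
    tests and single-CRU protocols.
    """
    np.random.seed(seed)
    r = np.zeros(20)
    cum = np.zeros((7, 4))
    tgt = np.zeros((7, 4), dtype=np.int8)
    nex = np.zeros(7, dtype=np.int8)
    vs_vi = P[P_VS] / P[P_VI]
    vp_vs = P[P_VP] / P[P_VS]
    vi_vnsr = P[P_VI] / P[P_VNSR]
    vjsr_vnsr = P[P_VJSR] / P[P_VNSR]
    vp_vjsr = P[P_VP] / P[P_VJSR]
    n_open = 0
    for ii in range(chan_state.size):
        if chan_state[ii] == 2:
            n_open += 1
    for step in range(n_steps):
        V = v_wave[step]
        ci_o, cs_o, cp_o, cnsr_o, cjsr_o = conc[0], conc[1], conc[2], conc[3], conc[4]
        ltcc_rate_vector(V, cp_o, n_open, P, r)
        _fill_exit_table(r, cum, tgt, nex)
        no = 0
        for ii in range(chan_state.size):
            s = chan_state[ii]
            x = np.random.random() / dt
            ne = nex[s]
            if x < cum[s, ne - 1]:
                for k in range(ne):
                    if x < cum[s, k]:
                        chan_state[ii] = tgt[s, k]
                        break
            if chan_state[ii] == 2:
                no += 1
        n_open = no
        i_ca = _ghk_current(V, cp_o, P)
        j_cal = -P[P_PA2UM] * i_ca * no / P[P_VP]
        _ryr_step(ryr, cp_o, cjsr_o, dt, P)
        j_rel = P[P_RYR_GREL] * ryr[1] * (cjsr_o - cp_o)
        i_dsi = (cs_o - ci_o) / P[P_TAUSI]
        i_tr = (cnsr_o - cjsr_o) / P[P_TAUTR]
        i_up = P[P_VUP] * ci_o ** 2 / (ci_o ** 2 + P[P_KUP] ** 2)
        j_ncx = _ncx_flux(V, cs_o, P)
        j_bk = P[P_GCABK]
        j_slcap = P[P_VSLCAP] * cs_o / (cs_o + P[P_KSLCAP])
        i_tci = P[P_KONT] * ci_o * (P[P_BT] - bti_bts[0]) - P[P_KOFFT] * bti_bts[0]
        i_tcs = P[P_KONT] * cs_o * (P[P_BT] - bti_bts[1]) - P[P_KOFFT] * bti_bts[1]
        b_i = _beta_inst(ci_o, P[P_BCAM], P[P_KCAM], P[P_BSR], P[P_KSR])
        b_s = _beta_inst(cs_o, P[P_BCAM], P[P_KCAM], P[P_BSR], P[P_KSR])
        b_jsr = 1.0 / (1.0 + P[P_BCSQN] * P[P_KCSQN] / (P[P_KCSQN] + cjsr_o) ** 2)
        conc[0] = ci_o + dt * b_i * (i_dsi * vs_vi - i_up - i_tci)
        conc[1] = cs_o + dt * b_s * (((cp_o - cs_o) / P[P_TAUP]) * vp_vs
                                     + j_ncx - i_dsi - i_tcs + j_bk - j_slcap)
        if cp_clamp:
            conc[2] = cp_wave[step]
        else:
            src = j_rel + j_cal
            cp_inf = cs_o + src * P[P_TAUP]
            conc[2] = cp_inf + (cp_o - cp_inf) * math.exp(-dt / P[P_TAUP])
        conc[3] = cnsr_o + dt * (i_up * vi_vnsr - i_tr * vjsr_vnsr)
        conc[4] = cjsr_o + dt * b_jsr * (i_tr - j_rel * vp_vjsr)
        bti_bts[0] += dt * i_tci
        bti_bts[1] += dt * i_tcs
        for k in range(5):
            if conc[k] < 0.0:
                conc[k] = 0.0
        out_cp[step] = conc[2]
        out_cjsr[step] = conc[4]
        out_nryr[step] = ryr[1]
        out_nltcc[step] = n_open
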