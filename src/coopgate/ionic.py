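"""Deterministic whole-cell AP + Ca-cycling model with cooperative gating.

A Shiferaw-type ventricular myocyte model: Hodgkin-Huxley sarcolemmal
currents (I_Na, I_to, I_Kr, I_Ks, I_Kp, I_K1, I_NaCa, I_CaL), a d*f*f_Ca
L-type Ca current, and a four-pool Ca-cycling subsystem (submembrane c_s,
cytosolic c_i, SR load c_j, delayed junctional load c_j' and a relaxation
equation for the release flux J_rel)::

    dV/dt      = -(I_ion + I_stim)/C_m
    dc_s/dt    = beta_s (v_i/v_s) [J_rel - (c_s - c_i)/tau_s + J_Ca + J_NaCa]
    dc_i/dt    = beta_i [(c_s - c_i)/tau_s - J_up]
    dc_j/dt    = -J_rel + J_up
    dc_j'/dt   = (c_j - c_j')/tau_a
    dJ_rel/dt  = g J_Ca Q(c_j') - J_rel/tau_r

Cooperative gating enters through the activation gate::

    dd/dt   = alpha_d gamma_d (1 - d) - beta_d d
    gamma_d = 1 + gain * w * sig(15 (po_Ca - po_x)) * sig(c_s - cs_x)

with ``po_Ca = d f f_Ca``.  With ``w = 0`` the model reduces exactly to the
uncoupled base model.  The release function Q is piecewise linear in the
delayed junctional SR load; its high-load slope ``u`` sets the steepness of
the SR release-load relation (the Ca-instability knob), while ``tau_f``
(the f-gate time constant) sets the steepness of APD restitution (the
voltage-instability knob).  The exponent ``gamma`` of Ca-dependent
inactivation selects positive (0.7) or negative (1.5) Ca_i -> V_m coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit

from . import constants as K
from .alternans import BeatSeries

__all__ = ["IonicParams", "IonicState", "gamma_d", "ionic_rhs", "integrate",
           "pace", "voltage_clamp", "sr_load_perturbation"]

# state-vector layout
(Y_V, Y_M, Y_H, Y_J, Y_XR, Y_XS, Y_ATO, Y_ITO,
 Y_D, Y_F, Y_FCA, Y_CS, Y_CI, Y_CJ, Y_CJP, Y_JREL, NY) = range(17)


@dataclass(frozen=True)
class IonicParams:
    """Parameters of the deterministic model (units in comments)."""

    g_na: float = K.IONIC_G_NA  # mS/uF
    g_k1: float = K.IONIC_G_K1
    g_kr: float = K.IONIC_G_KR
    g_ks: float = K.IONIC_G_KS
    g_to: float = K.IONIC_G_TO
    g_kp: float = K.IONIC_G_KP
    e_na: float = float(K.E_NA)  # mV
    e_k: float = float(K.E_K)
    g_ca: float = K.IONIC_GCA   # uM/ms per unit driving term
    tau_d_scale: float = K.IONIC_TAU_D_SCALE
    tau_f: float = K.IONIC_TAU_F      # ms
    tau_fca: float = K.IONIC_TAU_FCA  # ms
    cs_hat: float = K.IONIC_CS_HAT    # uM, f_Ca midpoint
    gamma: float = K.IONIC_GAMMA      # Ca-inactivation exponent
    tau_s: float = K.IONIC_TAU_S      # ms
    tau_a: float = K.IONIC_TAU_A      # ms
    tau_r: float = K.IONIC_TAU_R      # ms
    u: float = K.IONIC_U              # high-load slope of Q
    g_rel: float = K.IONIC_G_REL      # release gain
    q_c1: float = K.IONIC_Q_C1        # uM
    q_c2: float = K.IONIC_Q_C2        # uM
    v_up: float = K.IONIC_VUP         # uM/ms
    k_up: float = K.IONIC_KUP         # uM
    v_ncx: float = K.IONIC_V_NCX      # uM/ms
    vs_vi: float = K.IONIC_VS_VI
    alpha_conv: float = float(K.IONIC_ALPHA)  # (uM/ms -> A/F)
    ca_o: float = K.CA_O_MM           # mM
    rt_f: float = float(K.RT_F)
    w: float = 0.0                    # coupling strength
    coup_gain: float = K.IONIC_COUP_GAIN
    po_x: float = K.IONIC_PO_X
    cs_x: float = K.IONIC_CS_X

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be >= 0")
        for name in ("tau_f", "tau_fca", "tau_s", "tau_a", "tau_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    def with_(self, **kw) -> "IonicParams":
        return replace(self, **kw)


# parameter-array indices (must match the field order of IonicParams)
_PFIELDS = [f.name for f in fields(IonicParams)]
(IP_GNA, IP_GK1, IP_GKR, IP_GKS, IP_GTO, IP_GKP, IP_ENA, IP_EK,
 IP_GCA, IP_TAUD, IP_TAUF, IP_TAUFCA, IP_CSHAT, IP_GAMMA, IP_TAUS, IP_TAUA,
 IP_TAUR, IP_U, IP_GREL, IP_QC1, IP_QC2, IP_VUP, IP_KUP, IP_VNCX, IP_VSVI,
 IP_ALPHA, IP_CAO, IP_RTF, IP_W, IP_GAIN, IP_POX, IP_CSX) = range(len(_PFIELDS))


@dataclass
class IonicState:
    """Named view of the deterministic model's state vector."""

    y: np.ndarray

    @classmethod
    def resting(cls, v0: float = -86.4) -> "IonicState":
        y = np.zeros(NY)
        y[Y_V] = v0
        # gates at steady state for v0
        from ._kernels import _gate_rates
        gr = np.zeros(14)
        _gate_rates(v0, gr)
        y[Y_M] = gr[0] / (gr[0] + gr[1])
        y[Y_H] = 1.0 if gr[2] + gr[3] == 0 else gr[2] / (gr[2] + gr[3])
        y[Y_J] = 1.0 if gr[4] + gr[5] == 0 else gr[4] / (gr[4] + gr[5])
        y[Y_XR], y[Y_XS], y[Y_ATO], y[Y_ITO] = gr[6], gr[8], gr[10], gr[12]
        y[Y_D] = 1.0 / (1.0 + math.exp(-(v0 + 5.0) / 6.24))
        y[Y_F] = 1.0 / (1.0 + math.exp((v0 + 35.0) / 8.6))
        y[Y_FCA] = 1.0
        y[Y_CS] = 0.1
        y[Y_CI] = 0.1
        y[Y_CJ] = 100.0
        y[Y_CJP] = 100.0
        y[Y_JREL] = 0.0
        return cls(y)

    @property
    def vm(self) -> float:
        return float(self.y[Y_V])


def gamma_d(po_ca: float, c_s: float, params: IonicParams) -> float:
    """Cooperative-gating factor on the d-gate activation rate.

    Monotone nondecreasing in both the LTCC open probability
    ``po_Ca = d f f_Ca`` and the submembrane Ca; bounded by
    ``1 + gain * w``.
    """
    if not 0.0 <= po_ca <= 1.0:
        raise ValueError("po_ca must be in [0, 1]")
    if c_s < 0:
        raise ValueError("c_s must be >= 0")
    s1 = 1.0 / (1.0 + math.exp(-15.0 * (po_ca - params.po_x)))
    s2 = 1.0 / (1.0 + math.exp(-1.0 * (c_s - params.cs_x)))
    return 1.0 + params.coup_gain * params.w * s1 * s2


# gate bookkeeping for the Rush-Larsen update: indices and the (inf, tau)
# table filled by _rhs
GATES = (Y_M, Y_H, Y_J, Y_XR, Y_XS, Y_ATO, Y_ITO, Y_D, Y_F, Y_FCA)


@njit(cache=True)
def _rhs(y, t, p, istim, dy, gtab):
    """Right-hand side.  Continuous-state derivatives are written to ``dy``;
    every gate's steady state and time constant go to ``gtab`` (10 x 2, in
    GATES order) for the exact exponential (Rush-Larsen) update."""
    V = y[Y_V]
    rtf = p[IP_RTF]

    # --- LTCC gates -----------------------------------------------------
    d_inf = 1.0 / (1.0 + math.exp(-(V + 5.0) / 6.24))
    dv5 = V + 5.0
    if abs(dv5) < 1.0e-6:
        tau_d = 6.24 / 0.035 * d_inf / 6.24  # limit of the expression below
    else:
        tau_d = d_inf * (1.0 - math.exp(-dv5 / 6.24)) / (0.035 * dv5)
    tau_d *= p[IP_TAUD]
    alpha_d = d_inf / tau_d
    beta_d = (1.0 - d_inf) / tau_d
    po_ca = y[Y_D] * y[Y_F] * y[Y_FCA]
    if po_ca < 0.0:
        po_ca = 0.0
    s1 = 1.0 / (1.0 + math.exp(-15.0 * (po_ca - p[IP_POX])))
    s2 = 1.0 / (1.0 + math.exp(-(y[Y_CS] - p[IP_CSX])))
    g_d = 1.0 + p[IP_GAIN] * p[IP_W] * s1 * s2
    ad = alpha_d * g_d
    gtab[7, 0] = ad / (ad + beta_d)
    gtab[7, 1] = 1.0 / (ad + beta_d)

    f_inf = 1.0 / (1.0 + math.exp((V + 35.0) / 8.6))
    gtab[8, 0] = f_inf
    gtab[8, 1] = p[IP_TAUF]
    fca_inf = 1.0 / (1.0 + (y[Y_CS] / p[IP_CSHAT]) ** p[IP_GAMMA])
    gtab[9, 0] = fca_inf
    gtab[9, 1] = p[IP_TAUFCA]

    # --- L-type current flux --------------------------------------------
    z = V / rtf
    cs_mm = y[Y_CS] * 1.0e-3
    if abs(z) < 1.0e-7:
        ica_hat = 2.0 * (cs_mm - 0.34 * p[IP_CAO])
    else:
        e2z = math.exp(2.0 * z)
        ica_hat = 4.0 * z * (cs_mm * e2z - 0.34 * p[IP_CAO]) / (e2z - 1.0)
    j_ca = -p[IP_GCA] * y[Y_D] * y[Y_F] * y[Y_FCA] * ica_hat  # influx > 0
    i_cal = -2.0 * p[IP_ALPHA] * j_ca  # A/F, inward negative

    # --- NCX -------------------------------------------------------------
    eta = 0.35
    ksat = 0.1
    e1 = math.exp(eta * z)
    e2 = math.exp((eta - 1.0) * z)
    num = e1 * 1.0e3 * p[IP_CAO] - e2 * 2.744e6 * cs_mm  # Nai=10, Nao=140 baked
    den = (6.69922e5 + 2.744e6) * (1.38 + p[IP_CAO]) * (1.0 + ksat * e2)
    j_naca = p[IP_VNCX] * num / den  # uM/ms, >0 = Ca entry
    i_naca = p[IP_ALPHA] * j_naca

    # --- SR release and uptake -------------------------------------------
    cjp = y[Y_CJP]
    if cjp <= p[IP_QC1]:
        q = 0.0
    elif cjp <= p[IP_QC2]:
        q = cjp - p[IP_QC1]
    else:
        q = (p[IP_QC2] - p[IP_QC1]) + p[IP_U] * (cjp - p[IP_QC2])
    j_up = p[IP_VUP] * y[Y_CI] ** 2 / (y[Y_CI] ** 2 + p[IP_KUP] ** 2)
    trig = j_ca if j_ca > 0.0 else 0.0  # inward trigger only
    dy[Y_JREL] = p[IP_GREL] * 1.0e-3 * trig * q - y[Y_JREL] / p[IP_TAUR]

    # --- Ca pools ---------------------------------------------------------
    ci = y[Y_CI]
    cs = y[Y_CS]
    b_i = 1.0 / (1.0 + 24.0 * 7.0 / (7.0 + ci) ** 2
                 + 24.0 * 0.6 / (0.6 + ci) ** 2 + 70.0 * 0.6 / (0.6 + ci) ** 2)
    b_s = 1.0 / (1.0 + 24.0 * 7.0 / (7.0 + cs) ** 2
                 + 24.0 * 0.6 / (0.6 + cs) ** 2 + 70.0 * 0.6 / (0.6 + cs) ** 2)
    dy[Y_CS] = b_s / p[IP_VSVI] * (y[Y_JREL] - (cs - ci) / p[IP_TAUS]
                                   + j_ca + j_naca)
    dy[Y_CI] = b_i * ((cs - ci) / p[IP_TAUS] - j_up)
    dy[Y_CJ] = -y[Y_JREL] + j_up
    dy[Y_CJP] = (y[Y_CJ] - cjp) / p[IP_TAUA]

    # --- membrane currents ------------------------------------------------
    ek = p[IP_EK]
    i_na = p[IP_GNA] * y[Y_M] ** 3 * y[Y_H] * y[Y_J] * (V - p[IP_ENA])
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (V - ek - 59.215)))
    bk1 = ((0.49124 * math.exp(0.08032 * (V - ek + 5.476))
            + math.exp(0.06175 * (V - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (V - ek + 4.753))))
    i_k1 = p[IP_GK1] * ak1 / (ak1 + bk1) * (V - ek)
    rect = 1.0 / (1.0 + math.exp((V + 9.0) / 22.4))
    i_kr = p[IP_GKR] * y[Y_XR] * rect * (V - ek)
    i_ks = p[IP_GKS] * y[Y_XS] ** 2 * (V - ek)
    i_to = p[IP_GTO] * y[Y_ATO] * y[Y_ITO] * (V - ek)
    i_kp = p[IP_GKP] * (V - ek) / (1.0 + math.exp((7.488 - V) / 5.98))
    i_ion = i_na + i_k1 + i_kr + i_ks + i_to + i_kp + i_naca + i_cal
    dy[Y_V] = -(i_ion + istim)

    # --- HH gates ----------------------------------------------------------
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
    gtab[0, 0] = am / (am + bm)
    gtab[0, 1] = 1.0 / (am + bm)
    if ah + bh > 0.0:
        gtab[1, 0] = ah / (ah + bh)
        gtab[1, 1] = 1.0 / (ah + bh)
    else:
        gtab[1, 0] = y[Y_H]
        gtab[1, 1] = 1.0e9
    if aj + bj > 0.0:
        gtab[2, 0] = aj / (aj + bj)
        gtab[2, 1] = 1.0 / (aj + bj)
    else:
        gtab[2, 0] = y[Y_J]
        gtab[2, 1] = 1.0e9
    gtab[3, 0] = 1.0 / (1.0 + math.exp(-(V + 21.5) / 7.5))
    gtab[3, 1] = 30.0 + 250.0 / (1.0 + math.exp((V + 20.0) / 15.0))
    gtab[4, 0] = 1.0 / (1.0 + math.exp(-(V - 1.5) / 16.7))
    gtab[4, 1] = 50.0 + 350.0 / (1.0 + math.exp((V - 10.0) / 20.0))
    gtab[5, 0] = 1.0 / (1.0 + math.exp(-(V + 10.0) / 11.0))
    gtab[5, 1] = 2.0
    gtab[6, 0] = 1.0 / (1.0 + math.exp((V + 45.0) / 5.0))
    gtab[6, 1] = 25.0 + 30.0 / (1.0 + math.exp(-(V + 60.0) / 10.0))
    return i_cal


@njit(cache=True)
def _integrate(y, p, n_steps, dt, istim_arr, v_clamp, v_cmd, stride,
               out_y, out_ical):
    """Fixed-step integrator: forward Euler for the continuous states and
    the exact exponential (Rush-Larsen) update for every gate -- the
    standard scheme for stiff cardiac HH kinetics.  Records the state and
    I_CaL every ``stride`` steps; returns -1 on blow-up."""
    dy = np.zeros(NY)
    gtab = np.zeros((10, 2))
    for step in range(n_steps):
        if v_clamp:
            y[Y_V] = v_cmd[step]
        ical = _rhs(y, 0.0, p, istim_arr[step], dy, gtab)
        for i in (Y_V, Y_CS, Y_CI, Y_CJ, Y_CJP, Y_JREL):
            y[i] += dt * dy[i]
        for k in range(10):
            g = GATES[k]
            inf = gtab[k, 0]
            y[g] = inf + (y[g] - inf) * math.exp(-dt / gtab[k, 1])
        if v_clamp:
            y[Y_V] = v_cmd[step]
        for i in (Y_CS, Y_CI, Y_CJ, Y_CJP, Y_JREL):
            if y[i] < 0.0:
                y[i] = 0.0
        if step % stride == 0:
            k2 = step // stride
            for i in range(NY):
                out_y[k2, i] = y[i]
            out_ical[k2] = ical
        if not math.isfinite(y[Y_V]) or abs(y[Y_V]) > 500.0:
            return -1
    return 0


def ionic_rhs(state: IonicState, t: float, params: IonicParams,
              istim: float = 0.0) -> np.ndarray:
    """State derivatives (readable wrapper over the compiled RHS).

    Gate derivatives are reconstructed from their steady state and time
    constant, ``dx/dt = (x_inf - x)/tau`` -- algebraically identical to the
    alpha/beta form, including the gamma_d-modified d-gate.
    """
    dy = np.zeros(NY)
    gtab = np.zeros((10, 2))
    _rhs(state.y, t, params.to_array(), istim, dy, gtab)
    for k, g in enumerate(GATES):
        dy[g] = (gtab[k, 0] - state.y[g]) / gtab[k, 1]
    return dy


def integrate(state: IonicState, params: IonicParams, duration: float,
              dt: float = 0.01, stride: int = 50,
              istim: np.ndarray | None = None,
              v_cmd: np.ndarray | None = None):
    """Fixed-step RK4 integration; returns ``(t, Y, ical)`` at the stride.

    ``istim``: per-step stimulus current (A/F); ``v_cmd``: when given, the
    voltage is clamped to this per-step waveform.  Raises on numerical
    blow-up.
    """
    n_steps = int(round(duration / dt))
    ist = istim if istim is not None else np.zeros(n_steps)
    vcl = v_cmd is not None
    vc = v_cmd if vcl else np.zeros(n_steps)
    n_rec = (n_steps + stride - 1) // stride
    out_y = np.zeros((n_rec, NY))
    out_ical = np.zeros(n_rec)
    status = _integrate(state.y, params.to_array(), n_steps, dt, ist, vcl, vc,
                        stride, out_y, out_ical)
    if status != 0:
        raise FloatingPointError("numerical blow-up in ionic integration")
    t = np.arange(n_rec) * dt * stride
    return t, out_y, out_ical


def pace(params: IonicParams, pcl: float, n_beats: int,
         stim_amp: float = K.STIM_AMP, stim_dur: float = K.STIM_DUR,
         dt: float = 0.01, state: IonicState | None = None,
         apd_tol: float = 0.1, stride: int = 20):
    """Pace the model; returns ``(BeatSeries, IonicState, steady)``.

    ``steady`` is True when |APD_{n+2} - APD_n| < ``apd_tol`` ms held for
    the last 10 even beats (the documented steady-state criterion).
    """
    from .alternans import measure_apd, peak_per_beat

    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    st = state or IonicState.resting()
    n_steps_beat = int(round(pcl / dt))
    istim = np.zeros(n_steps_beat * n_beats)
    n_stim = int(round(stim_dur / dt))
    for b in range(n_beats):
        istim[b * n_steps_beat: b * n_steps_beat + n_stim] = stim_amp
    t, Y, ical = integrate(st, params, pcl * n_beats, dt=dt, stride=stride,
                           istim=istim)
    apd = measure_apd(t, Y[:, Y_V])
    peaks = peak_per_beat(t, Y[:, Y_CI], pcl)
    n = min(apd.size, peaks.size)
    series = BeatSeries(apd=apd[:n], ca_peak=peaks[:n], pcl=pcl)
    steady = False
    if apd.size >= 12:
        even = apd[apd.size % 2::2]
        if even.size >= 6 and np.all(np.abs(np.diff(even[-6:])) < apd_tol):
            steady = True
    return series, st, steady


def voltage_clamp(params: IonicParams, v_hold: float = -80.0,
                  v_test: float = 20.0, hold_ms: float = 500.0,
                  step_ms: float = 200.0, dt: float = 0.01, stride: int = 10):
    """Step-depolarisation clamp; returns ``(t, ical, Y)`` for the step
    interval only (holding interval discarded)."""
    st = IonicState.resting(v_hold)
    n_hold = int(round(hold_ms / dt))
    n_step = int(round(step_ms / dt))
    v_cmd = np.concatenate([np.full(n_hold, v_hold), np.full(n_step, v_test)])
    t, Y, ical = integrate(st, params, (n_hold + n_step) * dt, dt=dt,
                           stride=stride, v_cmd=v_cmd)
    m = t >= hold_ms
    return t[m] - hold_ms, ical[m], Y[m]


def sr_load_perturbation(params: IonicParams, pcl: float,
                         scales=(0.90, 0.95, 1.0, 1.05, 1.10),
                         n_settle: int = 400, dt: float = 0.01):
    """Ca_i -> V_m coupling measurement.

    Pace to steady state, then for each scale factor multiply the SR load
    (c_j, c_j') of the steady state, deliver one paced beat and record the
    changes in Ca-transient peak and APD relative to the unscaled beat.
    Returns a list of (dCa_peak, dAPD) points.
    """
    series, st, _ = pace(params, pcl, n_settle, dt=dt)
    base = st.y.copy()
    results = {}
    for s in scales:
        y = base.copy()
        y[Y_CJ] *= s
        y[Y_CJP] *= s
        one = IonicState(y)
        ser, _, _ = pace(params, pcl, 2, dt=dt, state=one)
        results[s] = (ser.ca_peak[0], ser.apd[0])
    ca0, apd0 = results[1.0]
    return [(results[s][0] - ca0, results[s][1] - apd0) for s in scales]
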