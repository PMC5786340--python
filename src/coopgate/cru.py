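"""The Ca release unit (CRU): five local Ca compartments, the 4-state
stochastic RyR cluster, and the lattice state container.

Each CRU holds cytosolic (``c_i``), submembrane (``c_s``), dyadic-cleft
(``c_p``), network-SR (``c_NSR``) and junctional-SR (``c_JSR``) Ca pools,
100 RyRs and one LTCC cluster.  The governing equations are::

    dc_i/dt   = beta_i (I_dsi v_s/v_i - I_up - I_TCi + I_ci)
    dc_s/dt   = beta_s (I_dps v_p/v_s + I_NCX - I_dsi - I_TCs + I_cs
                        - I_Cabk - I_SLCaP)
    dc_p/dt   = beta_p (I_r + I_CaL - I_dps)
    dc_NSR/dt = I_up v_i/v_NSR - I_tr v_JSR/v_NSR + I_cNSR
    dc_JSR/dt = beta_JSR (I_tr - I_r v_p/v_JSR)

with I_dsi = (c_s - c_i)/tau_si, I_dps = (c_p - c_s)/tau_p,
I_tr = (c_NSR - c_JSR)/tau_tr, and I_ci/I_cs/I_cNSR nearest-neighbour
diffusive couplings.  Sign convention: I_Cabk and I_SLCaP are written as
efflux-positive terms, so the background leak enters the c_s equation as a
negative I_Cabk.  This module holds the readable reference implementation;
the lattice simulations run on the compiled kernels in ``_kernels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from ._kernels import params_array, run_single_cru
from .geometry import CellGeometry, draw_cluster_sizes, resting_concentrations
from .ltcc import LtccParams, LtccClusterState

__all__ = ["RyrParams", "CruState", "CellState", "ryr_rates", "cru_rhs",
           "build_cell", "advance_cru_stochastic", "spark_trial"]

# RyR state order used everywhere: C, O, OI, CI
RYR_C, RYR_O, RYR_OI, RYR_CI = range(4)


@dataclass(frozen=True)
class RyrParams:
    """4-state RyR cluster parameters (spark-calibrated, see docs)."""

    nu: float = K.RYR_NU          # /ms maximal opening rate
    ka: float = K.RYR_KA          # uM cleft trigger midpoint (Hill-4)
    kj: float = K.RYR_KJ          # uM luminal midpoint
    hill: float = K.RYR_HILL      # luminal Hill exponent
    k_oc: float = K.RYR_K_OC      # /ms closing rate
    ki_cp: float = K.RYR_KI_CP    # /ms/uM inactivation coefficient
    k_io: float = K.RYR_K_IO      # /ms recovery rate


def ryr_rates(c_p: float, c_jsr: float, params: RyrParams | None = None):
    """Transition rates of the 4-state RyR scheme at (c_p, c_JSR).

    Returns a dict of the four elementary rates.  The opening rate
    ``k_co = nu H4(c_p) psi(c_JSR)`` (H4 a Hill-4 function of cleft Ca)
    increases with both cleft and luminal Ca
    and vanishes at c_p = 0 (no spontaneous trigger); the steep luminal
    factor ``psi`` terminates sparks by JSR depletion.
    """
    p = params or RyrParams()
    if c_p < 0 or c_jsr < 0:
        raise ValueError("concentrations must be >= 0")
    psi = c_jsr ** p.hill / (c_jsr ** p.hill + p.kj ** p.hill) if c_jsr > 0 else 0.0
    h4 = c_p ** 4 / (c_p ** 4 + p.ka ** 4)
    return {
        "k_co": p.nu * h4 * psi,
        "k_oc": p.k_oc,
        "k_oi": p.ki_cp * c_p,
        "k_io": p.k_io,
    }


@dataclass
class CruState:
    """State of a single CRU."""

    ci: float
    cs: float
    cp: float
    cnsr: float
    cjsr: float
    ryr_counts: np.ndarray          # 4 counts summing to n_ryr
    ltcc: LtccClusterState
    b_trpn_i: float = 10.0          # troponin-bound Ca, cytosol (uM)
    b_trpn_s: float = 10.0          # troponin-bound Ca, submembrane (uM)

    def __post_init__(self) -> None:
        self.ryr_counts = np.asarray(self.ryr_counts, dtype=np.int64)
        if self.ryr_counts.sum() != K.N_RYR_PER_CRU:
            raise ValueError(f"RyR counts must sum to {K.N_RYR_PER_CRU}")
        if min(self.ci, self.cs, self.cp, self.cnsr, self.cjsr) < 0:
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def resting(cls, cluster_size: int) -> "CruState":
        c = resting_concentrations()
        counts = np.array([K.N_RYR_PER_CRU, 0, 0, 0], dtype=np.int64)
        return cls(ci=c["ci"], cs=c["cs"], cp=c["cp"], cnsr=c["cnsr"],
                   cjsr=c["cjsr"], ryr_counts=counts,
                   ltcc=LtccClusterState.resting(cluster_size))


def _beta(c: float, pairs) -> float:
    return 1.0 / (1.0 + sum(B * Kd / (Kd + c) ** 2 for B, Kd in pairs))


def cru_rhs(state: CruState, neighbors, V: float,
            ltcc_params: LtccParams | None = None,
            ryr_params: RyrParams | None = None,
            disable_membrane_fluxes: bool = False,
            disable_pumps: bool = False):
    """Time derivatives of the five concentrations of one CRU.

    ``neighbors`` is a sequence of up to 6 ``(CruState | None, axis)`` pairs
    with ``axis`` 0 for longitudinal and 1/2 for transverse; ``None``
    entries are no-flux faces.  ``disable_membrane_fluxes`` zeroes I_NCX,
    I_Cabk, I_SLCaP and I_CaL (the closed-cell configuration used by the
    conservation checks); ``disable_pumps`` additionally zeroes SERCA
    uptake (the all-fluxes-off equilibrium check).
    """
    from .ltcc import single_channel_current

    lp = ltcc_params or LtccParams()
    i_dsi = (state.cs - state.ci) / K.TAU_SI
    i_dps = (state.cp - state.cs) / K.TAU_P
    i_tr = (state.cnsr - state.cjsr) / K.TAU_TR
    i_up = 0.0 if disable_pumps else (
        K.VUP * state.ci ** 2 / (state.ci ** 2 + K.KUP ** 2))
    i_tci = K.TRPN_KON * state.ci * (K.TRPN_B - state.b_trpn_i) - K.TRPN_KOFF * state.b_trpn_i
    i_tcs = K.TRPN_KON * state.cs * (K.TRPN_B - state.b_trpn_s) - K.TRPN_KOFF * state.b_trpn_s
    j_rel = K.RYR_G_REL * state.ryr_counts[RYR_O] * (state.cjsr - state.cp)

    if disable_membrane_fluxes:
        j_ncx = j_bk = j_slcap = j_cal = 0.0
    else:
        from ._kernels import _ncx_flux
        P = params_array(lp)
        j_ncx = _ncx_flux(V, state.cs, P)
        j_bk = K.G_CABK
        j_slcap = K.V_SLCAP * state.cs / (state.cs + K.K_SLCAP)
        i_ca = single_channel_current(V, state.cp, lp)
        j_cal = -K.PA_TO_UMMS * i_ca * state.ltcc.n_open / K.V_P

    taus = {0: (K.TAU_CI_L, K.TAU_CS_L, K.TAU_NSR_L),
            1: (K.TAU_CI_T, K.TAU_CS_T, K.TAU_NSR_T),
            2: (K.TAU_CI_T, K.TAU_CS_T, K.TAU_NSR_T)}
    i_ci = i_cs = i_nsr = 0.0
    for nb, axis in neighbors:
        if nb is None:
            continue
        t_ci, t_cs, t_nsr = taus[axis]
        i_ci += (nb.ci - state.ci) / t_ci
        i_cs += (nb.cs - state.cs) / t_cs
        i_nsr += (nb.cnsr - state.cnsr) / t_nsr

    pairs = ((K.BUF_CAM_B, K.BUF_CAM_K), (K.BUF_SR_B, K.BUF_SR_K))
    b_i = _beta(state.ci, pairs)
    b_s = _beta(state.cs, pairs)
    b_jsr = _beta(state.cjsr, ((K.BUF_CSQN_B, K.BUF_CSQN_K),))

    dci = b_i * (i_dsi * K.V_S / K.V_I - i_up - i_tci + i_ci)
    dcs = b_s * (i_dps * K.V_P / K.V_S + j_ncx - i_dsi - i_tcs + i_cs
                 + j_bk - j_slcap)
    dcp = j_rel + j_cal - i_dps   # beta_p = 1 (unbuffered cleft)
    dcnsr = i_up * K.V_I / K.V_NSR - i_tr * K.V_JSR / K.V_NSR + i_nsr
    dcjsr = b_jsr * (i_tr - j_rel * K.V_P / K.V_JSR)
    return dci, dcs, dcp, dcnsr, dcjsr


def advance_cru_stochastic(state: CruState, V: float, dt: float,
                           rng: np.random.Generator,
                           ltcc_params: LtccParams | None = None,
                           ryr_params: RyrParams | None = None) -> CruState:
    """One operator-split step of an isolated CRU (no neighbours).

    RyR counts move by binomial draws, the LTCC cluster by per-channel
    Bernoulli transitions, the concentrations by an explicit step of
    :func:`cru_rhs` (cleft by its exponential integrator).  Raises when a
    concentration would go negative (reduce dt).
    """
    from .ltcc import advance_cluster
    import copy

    rp = ryr_params or RyrParams()
    rates = ryr_rates(state.cp, state.cjsr, rp)
    counts = state.ryr_counts.copy()

    def move(i, j, k_rate, other_rate, other_j):
        tot = k_rate + other_rate
        if tot <= 0 or counts[i] == 0:
            return
        leave = rng.binomial(counts[i], 1.0 - np.exp(-tot * dt))
        first = rng.binomial(leave, k_rate / tot)
        counts[i] -= leave
        counts[j] += first
        counts[other_j] += leave - first

    move(RYR_C, RYR_O, rates["k_co"], rates["k_oi"], RYR_CI)
    move(RYR_O, RYR_C, rates["k_oc"], rates["k_oi"], RYR_OI)
    move(RYR_OI, RYR_CI, rates["k_oc"], rates["k_io"], RYR_O)
    move(RYR_CI, RYR_C, rates["k_io"], rates["k_co"], RYR_OI)

    new_ltcc = advance_cluster(state.ltcc, V, state.cp, dt, rng, ltcc_params)
    d = cru_rhs(state, (), V, ltcc_params, rp)
    new = copy.deepcopy(state)
    new.ryr_counts = counts
    new.ltcc = new_ltcc
    new.ci = state.ci + dt * d[0]
    new.cs = state.cs + dt * d[1]
    # cleft via exponential integrator toward quasi-steady value
    src = d[2] + (state.cp - state.cs) / K.TAU_P
    cp_inf = state.cs + src * K.TAU_P
    new.cp = cp_inf + (state.cp - cp_inf) * np.exp(-dt / K.TAU_P)
    new.cnsr = state.cnsr + dt * d[3]
    new.cjsr = state.cjsr + dt * d[4]
    new.b_trpn_i = state.b_trpn_i + dt * (
        K.TRPN_KON * state.ci * (K.TRPN_B - state.b_trpn_i) - K.TRPN_KOFF * state.b_trpn_i)
    new.b_trpn_s = state.b_trpn_s + dt * (
        K.TRPN_KON * state.cs * (K.TRPN_B - state.b_trpn_s) - K.TRPN_KOFF * state.b_trpn_s)
    if min(new.ci, new.cs, new.cp, new.cnsr, new.cjsr) < 0:
        raise ValueError("negative concentration after step: reduce dt")
    return new


@dataclass
class CellState:
    """Flat-array state of the whole CRU lattice plus the membrane."""

    geometry: CellGeometry
    cluster_sizes: np.ndarray
    chan_state: np.ndarray       # int8, CSR-packed per-channel labels
    chan_off: np.ndarray         # int64, length n_cru + 1
    ryr: np.ndarray              # int64 (n_cru, 4)
    ci: np.ndarray
    cs: np.ndarray
    cp: np.ndarray
    cnsr: np.ndarray
    cjsr: np.ndarray
    bti: np.ndarray
    bts: np.ndarray
    mem: np.ndarray              # [V, m, h, j, xr, xs, ato, ito]
    seed: int

    @property
    def n_cru(self) -> int:
        return self.geometry.n_cru

    def copy(self) -> "CellState":
        import dataclasses
        return dataclasses.replace(
            self, cluster_sizes=self.cluster_sizes.copy(),
            chan_state=self.chan_state.copy(), chan_off=self.chan_off.copy(),
            ryr=self.ryr.copy(), ci=self.ci.copy(), cs=self.cs.copy(),
            cp=self.cp.copy(), cnsr=self.cnsr.copy(), cjsr=self.cjsr.copy(),
            bti=self.bti.copy(), bts=self.bts.copy(), mem=self.mem.copy())


def build_cell(geometry: CellGeometry | None = None, seed: int = 0,
               v0: float = -85.0) -> CellState:
    """Construct a resting lattice; cluster sizes drawn from the rounded,
    clamped Gaussian rule; reproducible from ``seed``."""
    g = geometry or CellGeometry()
    sizes = draw_cluster_sizes(g, seed)
    n = g.n_cru
    off = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(sizes, out=off[1:])
    chan = np.zeros(off[-1], dtype=np.int8)  # all channels in C2
    c = resting_concentrations()
    ryr = np.zeros((n, 4), dtype=np.int64)
    ryr[:, RYR_C] = g.n_ryr
    mem = np.zeros(8)
    mem[0] = v0
    # HH gates at steady state for v0
    from ._kernels import _gate_rates
    gr = np.zeros(14)
    _gate_rates(v0, gr)
    mem[1] = gr[0] / (gr[0] + gr[1])
    mem[2] = gr[2] / (gr[2] + gr[3]) if gr[2] + gr[3] > 0 else 1.0
    mem[3] = gr[4] / (gr[4] + gr[5]) if gr[4] + gr[5] > 0 else 1.0
    mem[4], mem[5], mem[6], mem[7] = gr[6], gr[8], gr[10], gr[12]
    ci0 = c["ci"]
    b0 = K.TRPN_B * ci0 / (ci0 + K.TRPN_KOFF / K.TRPN_KON)
    return CellState(
        geometry=g, cluster_sizes=sizes, chan_state=chan, chan_off=off,
        ryr=ryr,
        ci=np.full(n, c["ci"]), cs=np.full(n, c["cs"]), cp=np.full(n, c["cp"]),
        cnsr=np.full(n, c["cnsr"]), cjsr=np.full(n, c["cjsr"]),
        bti=np.full(n, b0), bts=np.full(n, b0), mem=mem, seed=seed)


def spark_trial(seed: int, cp_amp: float = 15.0, cp_dur: float = 10.0,
                duration: float = 60.0, dt: float = 0.01,
                ltcc_params: LtccParams | None = None,
                overrides: dict | None = None) -> int:
    """Isolated-spark experiment on a single CRU: clamp c_p to ``cp_amp``
    (uM) for ``cp_dur`` ms at resting V and return the peak number of open
    RyRs.  Used by the spark-size calibration and acceptance checks."""
    lp = ltcc_params or LtccParams()
    P = params_array(lp, **(overrides or {}))
    n_steps = int(round(duration / dt))
    v_wave = np.full(n_steps, -80.0)
    cp_wave = np.full(n_steps, 0.1)
    cp_wave[:int(round(cp_dur / dt))] = cp_amp
    chan = np.zeros(1, dtype=np.int8)
    ryr = np.zeros(4, dtype=np.int64)
    ryr[RYR_C] = K.N_RYR_PER_CRU
    c = resting_concentrations()
    conc = np.array([c["ci"], c["cs"], c["cp"], c["cnsr"], c["cjsr"]])
    bb = np.array([10.0, 10.0])
    out = [np.zeros(n_steps) for _ in range(4)]
    run_single_cru(v_wave, True, cp_wave, n_steps, dt, seed,
                   chan, ryr, conc, bb, P, out[0], out[1], out[2], out[3])
    return int(out[2].max())
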