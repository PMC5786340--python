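"""The 7-state Markov model of the L-type Ca channel (LTCC) with
cooperative (coupled) gating, and stochastic simulation of a cluster.

States
------
``C2`` deep closed, ``C1`` proximal closed, ``O`` open, ``I1Ca``/``I2Ca``
Ca-inactivated, ``I1Ba``/``I2Ba`` voltage-inactivated ("Ba") states.

Cooperativity enters through two factors that depend on the number of open
channels ``N_L`` in the cluster and the dyadic-cleft Ca concentration
``c_p``::

    gamma_1 = 1 + w1 * sig(15 (N_L/3 - po_x)) * sig(1.0 (c_p - cp_x))
    gamma_2 = 1 + w2 * sig(15 (N_L/3 - po_x)) * sig(1.0 (c_p - cp_x))

with ``sig`` the logistic function.  ``gamma_1`` multiplies the activation
rate ``alpha`` (C2 -> C1) and ``gamma_2`` multiplies the opening rate ``r1``
(C1 -> O).  The reopening rates ``s2``/``s2'`` keep their base-rate
detailed-balance values, so cooperativity biases the cluster toward the
open state (longer cluster open dwell) rather than merely speeding the
C1 <-> O exchange.  With ``w1 = w2 = 0`` the scheme reduces exactly to the
uncoupled Markov chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as K

__all__ = [
    "LtccParams",
    "LtccRates",
    "LtccClusterState",
    "coupling_factors",
    "ltcc_rates",
    "generator_matrix",
    "single_channel_current",
    "advance_cluster",
    "cluster_current",
    "simulate_cluster",
    "opening_statistics",
]


@dataclass(frozen=True)
class LtccParams:
    """All constants of the LTCC scheme plus the coupling parameters."""

    tau_po: float = K.LTCC_TAU_PO
    r1: float = K.LTCC_R1
    r2: float = K.LTCC_R2
    s1_bar: float = K.LTCC_S1_BAR
    s1p: float = K.LTCC_S1P
    k1_bar: float = K.LTCC_K1_BAR
    k1p: float = K.LTCC_K1P
    k2: float = K.LTCC_K2
    k2p: float = K.LTCC_K2P
    cp_tilde: float = K.LTCC_CP_TILDE
    cp_minus: float = K.LTCC_CP_MINUS
    t_ca_max: float = K.LTCC_T_CA_MAX
    t_ba: float = K.LTCC_T_BA
    p_ca: float = K.LTCC_P_CA
    gamma_i: float = K.LTCC_GAMMA_I
    gamma_o: float = K.LTCC_GAMMA_O
    ca_o: float = K.CA_O_MM
    rt_f: float = K.RT_F
    w1: float = K.LTCC_W1
    w2: float = K.LTCC_W2
    po_x: float = K.LTCC_PO_X
    cp_x: float = K.LTCC_CP_X

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("coupling strengths w1, w2 must be >= 0")
        for name in ("tau_po", "r1", "r2", "s1_bar", "s1p", "k1_bar", "k1p",
                     "k2", "k2p", "cp_tilde", "cp_minus", "t_ca_max", "t_ba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be > 0")

    def uncoupled(self) -> "LtccParams":
        return replace(self, w1=0.0, w2=0.0)


@dataclass(frozen=True)
class LtccRates:
    """Instantaneous transition rates (per ms) at one (V, c_p, N_L)."""

    alpha: float   # C2 -> C1, includes gamma_1
    beta: float    # C1 -> C2
    r1: float      # C1 -> O, includes gamma_2
    r2: float      # O -> C1
    s1: float      # O -> I1Ca
    s2: float      # I1Ca -> O
    s1p: float     # O -> I1Ba
    s2p: float     # I1Ba -> O
    k1: float      # C1 -> I1Ca
    k2: float      # I1Ca -> C1
    k3: float      # I1Ca -> I2Ca
    k4: float      # I2Ca -> I1Ca
    k5: float      # I2Ca -> C2
    k6: float      # C2 -> I2Ca
    k1p: float     # C1 -> I1Ba
    k2p: float     # I1Ba -> C1
    k3p: float     # I1Ba -> I2Ba
    k4p: float     # I2Ba -> I1Ba
    k5p: float     # I2Ba -> C2
    k6p: float     # C2 -> I2Ba


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def coupling_factors(n_open: int, c_p: float, params: LtccParams) -> tuple[float, float]:
    """Cooperativity factors (gamma_1, gamma_2) at open count and cleft Ca.

    Both are 1 when coupling is disabled and saturate at ``1 + w`` when many
    neighbours are open in a Ca-rich cleft.
    """
    if n_open < 0:
        raise ValueError("n_open must be >= 0")
    if c_p < 0:
        raise ValueError("c_p must be >= 0")
    s = _logistic(15.0 * (n_open / 3.0 - params.po_x)) * _logistic(1.0 * (c_p - params.cp_x))
    return 1.0 + params.w1 * s, 1.0 + params.w2 * s


def ltcc_rates(V: float, c_p: float, n_open: int, params: LtccParams) -> LtccRates:
    """Evaluate every transition rate of the 7-state scheme.

    ``gamma_1`` is applied to ``alpha`` and ``gamma_2`` to ``r1``.
    ``c_p = 0`` makes
    ``f(c_p) = 0`` so the Ca-dependent rates vanish; this is allowed.
    """
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    if c_p < 0:
        raise ValueError("c_p must be >= 0")
    g1, g2 = coupling_factors(n_open, c_p, params)

    po_inf = _logistic(V / 8.0)
    alpha = po_inf / params.tau_po * g1
    beta = (1.0 - po_inf) / params.tau_po

    f_cp = 0.0 if c_p == 0.0 else 1.0 / (1.0 + (params.cp_tilde / c_p) ** 3)
    s1 = params.s1_bar * f_cp
    k1 = params.k1_bar * f_cp
    r1 = params.r1 * g2
    # detailed balance at base rates: s2 = s1 (k2/k1)/(r1/r2) with the
    # *uncoupled* r1 (cooperativity stabilises the open state)
    s2 = (params.s1_bar / params.k1_bar) * params.k2 * params.r2 / params.r1
    s2p = params.s1p * (params.k2p / params.k1p) * params.r2 / params.r1

    k3 = 1.0 / (3.0 * (1.0 + math.exp((V + 40.0) / 3.0)))
    k3p = k3
    r_v = 10.0 + 4954.0 * math.exp(V / 15.6)
    t_ca = params.t_ca_max / (1.0 + (c_p / params.cp_minus) ** 4)
    p_r = _logistic(-(V + 40.0) / 4.0)
    # P_s increases with V (depolarisation drives the deep inactivated
    # states): the orientation required for channels to recover at rest.
    p_s = _logistic((V + 40.0) / 11.32)
    tau_ca = (r_v - t_ca) * p_r + t_ca
    tau_ba = (r_v - params.t_ba) * p_r + params.t_ba
    k5 = (1.0 - p_s) / tau_ca
    k6 = f_cp * p_s / tau_ca
    k5p = (1.0 - p_s) / tau_ba
    k6p = p_s / tau_ba
    # k4 = k3 (alpha/beta)(k1/k2)(k5/k6); f(c_p) cancels between k1 and k6,
    # so the expression stays finite at c_p = 0.
    ab = math.exp(V / 8.0)  # alpha/beta, gamma-free
    k4 = k3 * ab * (params.k1_bar / params.k2) * (1.0 - p_s) / p_s
    k4p = k3p * ab * (params.k1p / params.k2p) * k5p / k6p
    return LtccRates(alpha=alpha, beta=beta, r1=r1, r2=params.r2,
                     s1=s1, s2=s2, s1p=params.s1p, s2p=s2p,
                     k1=k1, k2=params.k2, k3=k3, k4=k4, k5=k5, k6=k6,
                     k1p=params.k1p, k2p=params.k2p, k3p=k3p, k4p=k4p,
                     k5p=k5p, k6p=k6p)


#: (from_state, to_state, rate attribute) for every edge of the scheme
TRANSITIONS = (
    (K.LTCC_C2, K.LTCC_C1, "alpha"),
    (K.LTCC_C2, K.LTCC_I2CA, "k6"),
    (K.LTCC_C2, K.LTCC_I2BA, "k6p"),
    (K.LTCC_C1, K.LTCC_C2, "beta"),
    (K.LTCC_C1, K.LTCC_O, "r1"),
    (K.LTCC_C1, K.LTCC_I1CA, "k1"),
    (K.LTCC_C1, K.LTCC_I1BA, "k1p"),
    (K.LTCC_O, K.LTCC_C1, "r2"),
    (K.LTCC_O, K.LTCC_I1CA, "s1"),
    (K.LTCC_O, K.LTCC_I1BA, "s1p"),
    (K.LTCC_I1CA, K.LTCC_O, "s2"),
    (K.LTCC_I1CA, K.LTCC_C1, "k2"),
    (K.LTCC_I1CA, K.LTCC_I2CA, "k3"),
    (K.LTCC_I2CA, K.LTCC_I1CA, "k4"),
    (K.LTCC_I2CA, K.LTCC_C2, "k5"),
    (K.LTCC_I1BA, K.LTCC_O, "s2p"),
    (K.LTCC_I1BA, K.LTCC_C1, "k2p"),
    (K.LTCC_I1BA, K.LTCC_I2BA, "k3p"),
    (K.LTCC_I2BA, K.LTCC_I1BA, "k4p"),
    (K.LTCC_I2BA, K.LTCC_C2, "k5p"),
)


def generator_matrix(V: float, c_p: float, n_open: int, params: LtccParams) -> np.ndarray:
    """7x7 infinitesimal generator Q (rows sum to zero) at fixed conditions."""
    r = ltcc_rates(V, c_p, n_open, params)
    Q = np.zeros((7, 7))
    for i, j, name in TRANSITIONS:
        Q[i, j] = getattr(r, name)
    Q[np.diag_indices(7)] = -Q.sum(axis=1)
    return Q


def single_channel_current(V: float, c_p: float, params: LtccParams | None = None) -> float:
    """GHK-type single open-channel current (pA); inward is negative.

    ``i = 4 P_Ca z F (0.001 gamma_i c_p e^{2z} - gamma_o Ca_o)/(e^{2z} - 1)``
    with ``z = V F / (R T)``.  The removable singularity at V = 0 is handled
    analytically.
    """
    p = params or LtccParams()
    if c_p < 0:
        raise ValueError("c_p must be >= 0")
    z = V / p.rt_f
    a = 0.001 * p.gamma_i * c_p
    b = p.gamma_o * p.ca_o
    if abs(z) < 1.0e-7:
        return 2.0 * p.p_ca * K.FARADAY * (a - b)
    e2z = math.exp(2.0 * z)
    return 4.0 * p.p_ca * z * K.FARADAY * (a * e2z - b) / (e2z - 1.0)


@dataclass
class LtccClusterState:
    """Markov state of every channel in one cluster."""

    states: np.ndarray  # int array of per-channel state labels (0..6)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if not 1 <= self.states.size <= K.CLUSTER_MAX:
            raise ValueError(f"cluster size must be in [1, {K.CLUSTER_MAX}]")
        if np.any((self.states < 0) | (self.states > 6)):
            raise ValueError("invalid Markov state label")

    @classmethod
    def resting(cls, size: int) -> "LtccClusterState":
        return cls(np.full(size, K.LTCC_C2, dtype=np.int64))

    @property
    def n_open(self) -> int:
        return int(np.count_nonzero(self.states == K.LTCC_O))

    @property
    def size(self) -> int:
        return self.states.size


def _exit_table(rates: LtccRates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state arrays of (cumulative rate, target state) for sampling."""
    n_exit = np.zeros(7, dtype=np.int64)
    cum = np.zeros((7, 4))
    tgt = np.zeros((7, 4), dtype=np.int64)
    for i, j, name in TRANSITIONS:
        k = n_exit[i]
        prev = cum[i, k - 1] if k > 0 else 0.0
        cum[i, k] = prev + getattr(rates, name)
        tgt[i, k] = j
        n_exit[i] += 1
    return cum, tgt, n_exit


def advance_cluster(state: LtccClusterState, V: float, c_p: float, dt: float,
                    rng: np.random.Generator,
                    params: LtccParams | None = None) -> LtccClusterState:
    """Advance every channel of the cluster by one fixed step ``dt``.

    Rates are evaluated once with the open count at the start of the step
    (explicit update), so the outcome is order-independent within the step.
    Each channel makes at most one transition, with probability rate*dt per
    edge.  Raises ``ValueError`` when the largest total exit rate times
    ``dt`` reaches 0.1 -- substep with a smaller ``dt`` in that case.
    """
    p = params or LtccParams()
    rates = ltcc_rates(V, c_p, state.n_open, p)
    cum, tgt, n_exit = _exit_table(rates)
    max_exit = max(cum[i, n_exit[i] - 1] for i in range(7) if n_exit[i] > 0)
    if max_exit * dt >= 0.1:
        raise ValueError(
            f"dt = {dt} too large: max total exit rate {max_exit:.3g}/ms gives "
            f"rate*dt = {max_exit * dt:.3g} >= 0.1; use substeps")
    u = rng.random(state.size)
    new = state.states.copy()
    for idx in range(state.size):
        s = state.states[idx]
        ne = n_exit[s]
        if ne == 0:
            continue
        x = u[idx] / dt  # compare against cumulative rates directly
        if x < cum[s, ne - 1]:
            for k in range(ne):
                if x < cum[s, k]:
                    new[idx] = tgt[s, k]
                    break
    return LtccClusterState(new)


def cluster_current(state: LtccClusterState, V: float, c_p: float,
                    params: LtccParams | None = None) -> float:
    """Cluster current ``I = i_Ca * N_L`` (pA)."""
    n = state.n_open
    if n == 0:
        return 0.0
    return single_channel_current(V, c_p, params) * n


def simulate_cluster(size: int, V: float, c_p: float, duration: float, dt: float,
                     seed: int, params: LtccParams | None = None,
                     initial: LtccClusterState | None = None,
                     record_states: bool = False):
    """Simulate a cluster under clamped (V, c_p); returns the n_open trace.

    Pure-python reference path used for oracle tests and small protocols;
    the lattice simulations use the compiled kernels instead.

    Returns ``(t, n_open)`` or ``(t, n_open, states)`` with ``states`` the
    (n_steps+1, size) per-channel label history when ``record_states``.
    """
    p = params or LtccParams()
    rng = np.random.default_rng(seed)
    state = initial or LtccClusterState.resting(size)
    n_steps = int(round(duration / dt))
    n_open = np.empty(n_steps + 1, dtype=np.int64)
    n_open[0] = state.n_open
    hist = np.empty((n_steps + 1, size), dtype=np.int64) if record_states else None
    if record_states:
        hist[0] = state.states
    for k in range(1, n_steps + 1):
        state = advance_cluster(state, V, c_p, dt, rng, p)
        n_open[k] = state.n_open
        if record_states:
            hist[k] = state.states
    t = np.arange(n_steps + 1) * dt
    if record_states:
        return t, n_open, hist
    return t, n_open


def opening_statistics(trace: np.ndarray, dt: float):
    """Event statistics of an ``n_open`` time series sampled at fixed dt.

    An *event* is a maximal run of samples with ``n_open >= 1``.  Returns
    ``(max_counts, dwell_times)`` where ``max_counts[k]`` is the maximum
    simultaneous open count during event k and ``dwell_times[k]`` its
    duration in ms (number of samples in the run times dt).
    """
    trace = np.asarray(trace)
    if trace.size == 0:
        return np.array([], dtype=np.int64), np.array([])
    active = trace >= 1
    # run boundaries
    edges = np.diff(active.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(trace.size)
    max_counts = np.array([trace[a:b].max() for a, b in zip(starts, ends)],
                          dtype=np.int64)
    dwell = np.array([(b - a) * dt for a, b in zip(starts, ends)])
    return max_counts, dwell
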