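"""Physical constants and adopted base-model parameter sets.

Every number that the cooperative-gating study itself does not introduce is
collected here, in one place, so the provenance of each constant is explicit:

* ``LTCC_*`` -- the 7-state L-type Ca channel Markov scheme uses the rabbit
  ventricular formulation (Mahajan-type rate notation).  Rate prefactors that
  the cooperative-gating formulation restates (``s1 = 0.02 f(c_p)``,
  ``k1 = 0.03 f(c_p)``, the 114-ms ceiling of the Ca-inactivation recovery
  time) are kept at those restated values.
* ``RYR_*`` / ``CRU_*`` -- the Ca release unit (100 RyRs, five local Ca
  compartments) follows the Restrepo-type subcellular architecture.  The RyR
  open probability is deliberately calibrated so that an isolated spark
  recruits 5-10 of the 100 RyRs (see docs/methods.md, "Spark calibration").
* ``MEM_*`` -- sarcolemmal Na/K current formulations are standard
  Luo-Rudy-type kinetics; conductances are calibrated to give a ventricular
  AP of roughly 200-250 ms at a 300-ms pacing cycle length.
* ``IONIC_*`` -- the deterministic (Shiferaw-type) whole-cell model's
  Ca-cycling constants.

Units follow cardiac-modelling convention: time in ms, voltage in mV,
concentrations in uM unless suffixed ``_MM`` (mM), volumes in um^3,
currents in A/F (whole cell) or pA (single channel), fluxes in uM/ms.
"""

import numpy as np

# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------
FARADAY = 96.485       # C / mmol
GAS_R = 8.314          # J / (mol K)
TEMPERATURE = 308.0    # K (35 C, rabbit ventricle convention)
#: thermal voltage RT/F in mV
RT_F = 1000.0 * GAS_R * TEMPERATURE / (FARADAY * 1000.0)  # = 26.54 mV

# ---------------------------------------------------------------------------
# LTCC 7-state Markov scheme
# ---------------------------------------------------------------------------
# state encoding used throughout the package
LTCC_C2, LTCC_C1, LTCC_O, LTCC_I1CA, LTCC_I2CA, LTCC_I1BA, LTCC_I2BA = range(7)
LTCC_STATE_NAMES = ("C2", "C1", "O", "I1Ca", "I2Ca", "I1Ba", "I2Ba")

LTCC_TAU_PO = 1.0        # ms, activation time constant tau_po
LTCC_R1 = 0.30           # /ms, C1 -> O
LTCC_R2 = 3.0            # /ms, O -> C1
LTCC_S1_BAR = 0.02       # /ms, O -> I1Ca prefactor (times f(c_p))
LTCC_S1P = 0.00195       # /ms, O -> I1Ba
LTCC_K1_BAR = 0.03       # /ms, C1 -> I1Ca prefactor (times f(c_p))
LTCC_K1P = 0.00413       # /ms, C1 -> I1Ba
LTCC_K2 = 1.03615e-4     # /ms, I1Ca -> C1
LTCC_K2P = 0.00224       # /ms, I1Ba -> C1
LTCC_CP_TILDE = 1.2      # uM, midpoint of f(c_p) = 1/(1+(cp~/cp)^3)
LTCC_CP_MINUS = 6.09365  # uM, midpoint of the T_Ca recovery-time relation
LTCC_T_CA_MAX = 114.0    # ms, ceiling of T_Ca(c_p)
LTCC_T_BA = 450.0        # ms, recovery time of the Ba branch

# single-channel GHK-type current
LTCC_P_CA = 0.004        # flux constant scaled so open-channel current is in pA
LTCC_GAMMA_I = 1.0       # inner activity coefficient
LTCC_GAMMA_O = 0.341     # outer activity coefficient
CA_O_MM = 1.8            # mM, extracellular Ca

# cooperative-gating defaults (calibrated; see docs/methods.md).  With these
# values a -80 -> +20 mV step on the lattice gives a peak I_CaL about 1.5x
# the uncoupled peak and shifts the activation midpoint ~5 mV leftward.
LTCC_W1 = 10.0           # coupling strength on the activation rate alpha
LTCC_W2 = 10.0           # coupling strength on the opening rate r1
LTCC_PO_X = 0.10         # open-count sensitivity midpoint (N_L/3 scale)
LTCC_CP_X = 100.0        # uM, cleft-Ca sensitivity midpoint

# ---------------------------------------------------------------------------
# CRU geometry and local volumes
# ---------------------------------------------------------------------------
GRID_NX, GRID_NY, GRID_NZ = 65, 27, 11   # default lattice (19,305 CRUs)
DX_LONG = 1.84     # um, longitudinal CRU spacing
DX_TRANS = 0.90    # um, transverse CRU spacing
CLUSTER_MEAN = 10.0
CLUSTER_SD = 3.0
CLUSTER_MIN, CLUSTER_MAX = 1, 25
N_RYR_PER_CRU = 100

# local compartment volumes per CRU (um^3)
V_I = 1.00         # cytosol
V_S = 0.10         # submembrane shell
V_P = 0.00126      # dyadic cleft
V_NSR = 0.050      # network SR
V_JSR = 0.020      # junctional SR

# pA -> uM/ms conversion for a divalent current entering volume v (um^3):
# J = PA_TO_UMMS * i / v
PA_TO_UMMS = 1.0e6 / (2.0 * FARADAY * 1000.0)  # = 5.182

# ---------------------------------------------------------------------------
# intra/inter-CRU Ca transport
# ---------------------------------------------------------------------------
TAU_P = 0.10       # ms, cleft <-> submembrane
TAU_SI = 1.5       # ms, submembrane <-> cytosol
TAU_TR = 30.0      # ms, NSR -> JSR refill
# nearest-neighbour diffusion relaxation times (per neighbour pair)
TAU_CI_L, TAU_CI_T = 5.6, 1.35     # cytosol, longitudinal / transverse
TAU_CS_L, TAU_CS_T = 5.6, 1.35     # submembrane
TAU_NSR_L, TAU_NSR_T = 28.0, 6.8   # network SR

# ---------------------------------------------------------------------------
# RyR cluster (4-state: C, O, CI, OI) -- spark-calibrated
# ---------------------------------------------------------------------------
RYR_NU = 0.034     # /ms, maximal per-channel opening rate
RYR_KA = 8.0       # uM, cleft-Ca trigger midpoint (Hill-4 activation)
RYR_KJ = 500.0     # uM, luminal-sensitivity midpoint psi = cj^h/(cj^h+Kj^h)
RYR_HILL = 12.0    # luminal Hill exponent (steep: terminates sparks)
RYR_K_OC = 0.6     # /ms, O -> C (~1.7 ms mean open time)
RYR_KI_CP = 2.0e-3 # /ms/uM, Ca-dependent inactivation rate coefficient
RYR_K_IO = 0.0075  # /ms, recovery from inactivation (~130 ms refractoriness)
RYR_G_REL = 0.80   # /ms, per-open-RyR release flux coefficient (cleft volume)

# ---------------------------------------------------------------------------
# Ca buffering
# ---------------------------------------------------------------------------
BUF_CAM_B, BUF_CAM_K = 24.0, 7.0       # uM, calmodulin (instantaneous)
BUF_SR_B, BUF_SR_K = 24.0, 0.6         # uM, SR-membrane sites (instantaneous)
BUF_CSQN_B, BUF_CSQN_K = 5000.0, 600.0 # uM, calsequestrin in JSR
TRPN_B = 70.0       # uM, troponin C (time-dependent)
TRPN_KON = 0.0327   # /uM/ms
TRPN_KOFF = 0.0196  # /ms

# ---------------------------------------------------------------------------
# pumps, exchanger, background fluxes (stochastic model, per-CRU)
# ---------------------------------------------------------------------------
VUP = 0.60         # uM/ms, SERCA maximum (acts on c_i)
KUP = 0.5          # uM, SERCA half-activation
V_NCX = 500.0      # uM/ms, NCX scale (acts on c_s)
NCX_KSAT = 0.1
NCX_ETA = 0.35
NCX_KMNA = 87.5    # mM
NCX_KMCA = 1.38    # mM
NA_I = 10.0        # mM (fixed)
NA_O = 140.0       # mM
G_CABK = 0.0015    # uM/ms, background sarcolemmal Ca leak into c_s
V_SLCAP = 0.06     # uM/ms, sarcolemmal Ca pump maximum
K_SLCAP = 0.3      # uM

# ---------------------------------------------------------------------------
# membrane (whole cell)
# ---------------------------------------------------------------------------
CM_PER_CRU = 7.77e-3   # pF per CRU (150 pF over the default 19,305-CRU cell)
K_O, K_I = 5.4, 140.0  # mM
E_K = RT_F * np.log(K_O / K_I)       # ~ -86.4 mV
E_NA = RT_F * np.log(NA_O / NA_I)    # ~ +70 mV

G_NA = 16.0
G_K1 = 0.42
G_KR = 0.032
G_KS = 0.025
G_TO = 0.05
G_KP = 0.004
STIM_AMP = -80.0   # A/F
STIM_DUR = 1.0     # ms

# ---------------------------------------------------------------------------
# deterministic (Shiferaw-type) ionic model
# ---------------------------------------------------------------------------
# sarcolemmal conductances of the deterministic model (tuned separately
# from the lattice membrane: the smooth d-f-fCa L-type current carries more
# window current near -10 mV and needs a stronger delayed rectifier)
IONIC_G_NA = 16.0
IONIC_G_K1 = 0.42
IONIC_G_KR = 0.10
IONIC_G_KS = 0.025
IONIC_G_TO = 0.05
IONIC_G_KP = 0.004
IONIC_CM = 150.0        # pF
IONIC_V_I = 1.93e4      # um^3 cytosol
IONIC_VS_VI = 0.1       # v_s / v_i
# alpha = F v_i / C_m, converts uM/ms (cytosolic flux) to A/F
IONIC_ALPHA = FARADAY * 1000.0 * (IONIC_V_I * 1.0e-15) / (IONIC_CM * 1.0e-12) * 1.0e-3

IONIC_GCA = 2.4         # trigger-flux scale (uM/ms per unit driving term)
IONIC_TAU_D_SCALE = 12.0
IONIC_TAU_F = 45.0      # ms, default f-gate time constant (varied in scans)
IONIC_TAU_FCA = 8.0     # ms
IONIC_CS_HAT = 1.7      # uM, f_Ca midpoint
IONIC_GAMMA = 0.7       # Ca-inactivation exponent (0.7 positive, 1.5 negative)
IONIC_TAU_S = 4.0       # ms, submembrane <-> cytosol
IONIC_TAU_A = 100.0     # ms, c_j' relaxation toward c_j
IONIC_TAU_R = 30.0      # ms, release-flux relaxation
IONIC_U = 3.0           # high-load slope of the release function Q
IONIC_G_REL = 3.0       # release gain g
IONIC_Q_C1 = 50.0       # uM, Q lower breakpoint
IONIC_Q_C2 = 80.0       # uM, Q upper breakpoint
IONIC_VUP = 0.40        # uM/ms
IONIC_KUP = 0.5         # uM
IONIC_V_NCX = 180.0     # uM/ms (cytosol-scaled NCX flux scale)

# cooperative gating in the ionic model: gamma_d = 1 + gain*w*sig*sig.
# The printed prefactor of 0.01 cannot reproduce the reported w-dependent
# effects (1.5-fold peak I_CaL at w = 1); the package default is 1.0.
# See docs/methods.md, "The gamma_d gain".
IONIC_COUP_GAIN = 3.0
IONIC_PO_X = 0.02       # open-probability sensitivity midpoint
IONIC_CS_X = 0.2        # uM, submembrane-Ca sensitivity midpoint
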