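# Methods

`coopgate` models cooperative (coupled) gating of clustered L-type Ca²⁺
channels (LTCCs) in ventricular myocytes and its consequences for cardiac
alternans, at three levels of description: a stochastic subcellular model
(Markov channels on a lattice of Ca²⁺ release units), a deterministic
whole-cell ionic model, and a closed-form two-variable map theory. This
note records the model equations as implemented, the calibrations and
numerical choices, and what the synthetic/desk-scale configurations do and
do not establish.

## 1. Stochastic model

### 1.1 LTCC Markov scheme

Each channel occupies one of seven states — two closed (C2, C1), one open
(O), two Ca²⁺-inactivated (I1Ca, I2Ca) and two voltage-inactivated "Ba"
states (I1Ba, I2Ba). Voltage-dependent activation enters through

    po∞(V) = 1/(1 + e^(−V/8)),   α = po∞/τpo,  β = (1 − po∞)/τpo,  τpo = 1 ms,

Ca²⁺-dependent inactivation through f(c_p) = 1/(1 + (c̃p/c_p)³) with the
cleft Ca concentration c_p, s1 = 0.02·f, k1 = 0.03·f, and recovery through
voltage-partition functions

    P_r = 1/(1 + e^{(V+40)/4}),      (decreasing in V)
    P_s = 1/(1 + e^{−(V+40)/11.32}), (increasing in V)

with recovery times τCa = (R(V) − T_Ca)P_r + T_Ca,
τBa = (R(V) − T_Ba)P_r + T_Ba, R(V) = 10 + 4954·e^{V/15.6},
T_Ca = 114/(1 + (c_p/c_p⁻)⁴), T_Ba = 450 ms. Remaining rates follow
detailed balance (s2 from s1, k4 from k3; see `ltcc.py`). Both partition
functions are ½ at V = −40 mV. The orientation of P_s (increasing with
depolarisation) is the one under which channels *recover* at the resting
potential; with the opposite orientation the entire population inactivates
irreversibly at rest and no repeated APs are possible, so that variant is
not viable.

Cooperativity multiplies the activation rate α by γ₁ and the opening rate
r1 by γ₂, with

    γ = 1 + w · σ(15(N_L/3 − po_x)) · σ(c_p − cp_x),

σ the logistic function and N_L the cluster's instantaneous open count
(taken at the start of each time step; explicit, order-independent
update). γ ∈ [1, 1+w], nondecreasing in N_L and c_p; w₁ = w₂ = 0 recovers
the uncoupled chain bit-exactly. N_L/3 is used exactly as written (not
normalised by cluster size).

**Design choice — γ₂ and detailed balance.** The reopening rates s2/s2′
are kept at their *base-rate* detailed-balance values rather than being
recomputed with γ₂·r1. Folding γ₂ into the balance expressions makes the
stationary open probability *decrease* with coupling strength (faster
opening is exactly compensated by suppressed reopening from I1Ca), which
contradicts the defining phenomenology of coupled gating — longer cluster
open dwell times and more frequent multi-channel openings. With γ₂ as a
pure kinetic bias toward the open state, the mean open probability and the
frequency of ≥2-channel events both increase monotonically with w (tested).

**Calibration of w₁, w₂, po_x, cp_x.** These are not printed anywhere;
they control how strongly an open, Ca-rich cluster recruits its
neighbours. Two observables pin them down: a −80 → +20 mV step should
raise the peak whole-cell I_CaL about 1.5-fold, and the activation curve
should shift several mV leftward. A purely multiplicative speed-up
amplifies the current nearly uniformly across voltages and produces no
shift; the shift requires a *regenerative* regime in which one opening
ignites the rest of the cluster preferentially at negative potentials.
The single-channel GHK current supplies the voltage selectivity: one open
channel drives the cleft to ~600 µM at −20 mV but only ~80 µM at +20 mV,
so placing the Ca-sensitivity midpoint between those values
(cp_x = 100 µM) lets singleton openings engage the coupling at negative
but not positive potentials. Defaults: w₁ = w₂ = 10, po_x = 0.1
(a single open neighbour nearly saturates the open-count factor),
cp_x = 100 µM. With these, the step-clamp peak ratio is ≈1.5 and the
fitted activation midpoint moves ≈6–8 mV leftward on the desk-scale
lattice. They are ordinary parameters of `LtccParams`.

### 1.2 Single-channel current

GHK-type flux, i = 4·P_Ca·z·F·(0.001·γ_i·c_p·e^{2z} − γ_o·[Ca]_o)/(e^{2z} − 1),
z = VF/RT, with γ_i = 1, γ_o = 0.341, [Ca]_o = 1.8 mM, and P_Ca scaled so
the open-channel current is on the physiological pA scale (≈ −0.2 pA at
+20 mV). The V = 0 singularity is removable and handled analytically.
Cluster current is i·N_L.

### 1.3 Ca²⁺ release units and lattice

The default cell is a 65×27×11 lattice (19,305 CRUs; 1.84 µm longitudinal,
0.9 µm transverse spacing). Each CRU carries 100 RyRs, an LTCC cluster
whose size is drawn from a rounded Gaussian (mean 10, SD 3, clamped to
[1, 25]), and five Ca²⁺ pools: cytosolic c_i, submembrane c_s, dyadic
cleft c_p, network-SR c_NSR and junctional-SR c_JSR, governed by the five
local balance equations in `cru.py` (volume-ratio factors, instantaneous
buffering factors β, troponin as a time-dependent buffer, nearest-neighbour
diffusion for c_i, c_s, c_NSR with separate longitudinal/transverse
relaxation times, no-flux boundaries).

The RyR cluster is a four-state scheme (closed, open, open-inactivated,
closed-inactivated). Opening is driven jointly by cleft and luminal Ca:

    k_CO = ν · c_p⁴/(c_p⁴ + K_a⁴) · ψ(c_JSR),   ψ = c_JSR^h/(c_JSR^h + K_j^h),

with closing k_OC = 0.6/ms, Ca-driven inactivation k_inact = k_i·c_p
(k_i = 0.002 /µM/ms) and recovery k_rec = 0.0075/ms (~130 ms
refractoriness). The saturating (Hill-4) trigger replaces a quadratic
law: at the reduced spark size modelled here (5–10 open RyRs out of 100,
rather than ~100) a quadratic opening law cannot give both a quiet
diastole and a reliable spark; the Hill form provides a trigger threshold
(K_a = 8 µM) between diastolic c_p (~0.1 µM) and the cleft Ca reached
during LTCC openings (tens of µM). The steep luminal factor ψ
(K_j = 500 µM, h = 12) terminates sparks by local JSR depletion and makes
whole-cell release load-sensitive, and the Ca-driven refractoriness
carries release memory from beat to beat — together the substrate of
Ca-driven alternans. The coupled cell, with its larger trigger, deeper
JSR depletion and longer APD (shorter diastole), engages this memory at a
300-ms cycle length; the uncoupled cell does not, which is exactly the
coupling-dependence of alternans the model exists to exhibit.

**Spark calibration.** ν (= 0.034/ms) and the per-open-RyR release
conductance were fixed by a seed-scanned grid so that an isolated spark —
one CRU, cleft Ca clamped to a 15–60 µM pulse — opens 5–10 of the 100
RyRs for the central 90 % of trials (mean ≈ 7). This calibration is
insensitive to the trigger amplitude over that range.

### 1.4 Membrane and whole-cell coupling

Sarcolemmal Na⁺/K⁺ currents use standard Luo–Rudy-type kinetics (I_Na,
I_K1, I_Kr, I_Ks, I_to, I_Kp) with conductances calibrated for an AP of
roughly 180–230 ms at a 300-ms pacing cycle length; NCX acts on each CRU's
submembrane pool and the whole-cell I_CaL is the capacitance-normalised
sum of cluster currents (7.77 fF membrane per CRU, 150 pF for the full
cell). Under voltage clamp the commanded waveform is imposed exactly.

### 1.5 Numerics

Fixed-step operator splitting at dt = 0.01 ms (clamp protocols) or
0.02 ms (pacing): per-channel Bernoulli transitions with rates frozen at
the start-of-step state, binomial draws for the RyR counts (exact
exponential per-transition probabilities with competing risks), forward
Euler for the concentrations, an exponential (exact linear-part)
integrator for the stiff cleft pool, and Rush–Larsen updates for the HH
gates. Negative concentrations are clamped to zero and counted; runs
report the count (zero in all shipped configurations). Master-equation
oracles (1-channel and exact 2-channel joint chains) bound the
discretisation error of the channel update. All randomness derives from
one seed; identical seeds give bit-identical trajectories.

Desk scales: tests and the acceptance protocols run 512-CRU (16×8×4) or
smaller lattices. These preserve per-CRU physics and capacitance density;
whole-cell current noise scales like 1/√N, so desk-scale traces are
noisier than full-cell ones, and peak-based comparisons use short boxcar
smoothing (2 ms) to suppress single-channel shot noise. Paced beats are
summarised by a stimulus-window-aligned APD (censored at the cycle length
when a long beat fails to repolarise before the next stimulus, as happens
in strong 2:2 alternans), which keeps the alternation phase of every beat
even when the rhythm is irregular.

## 2. Deterministic (ionic) model

A Shiferaw-type whole-cell model (`ionic.py`): Luo–Rudy-type Na⁺/K⁺
currents, an L-type current J_CaL = −g_Ca·d·f·f_Ca·i_Ca with the GHK-type
driving term i_Ca evaluated at the submembrane Ca, and a four-pool Ca
subsystem (c_s, c_i, SR load c_j, delayed junctional load c_j′) with a
relaxation equation for the release flux:

    dJ_rel/dt = g·J_Ca·Q(c_j′) − J_rel/τ_r.

Q is piecewise linear in the delayed load: zero below 50 µM, unit slope to
80 µM, slope u above. The upper breakpoint sits *below* the steady-state
operating load (~90–130 µM cytosol-scaled) so that u is the active
release-load slope; with a higher breakpoint the load self-regulates below
it and u has no effect at all. τ_a = 100 ms delays c_j′ behind c_j,
providing the beat-to-beat memory of the Ca map. Voltage-dependent
inactivation f has time constant τ_f (the APD-restitution steepness knob);
Ca-dependent inactivation is f_Ca∞ = 1/(1 + (c_s/ĉ_s)^γ) with τ_fCa = 8 ms,
ĉ_s = 1.7 µM. γ = 0.7 gives NCX-dominated (positive) Ca→V coupling,
γ = 1.5 inactivation-dominated (negative) coupling, as probed by the
SR-load perturbation protocol (±5 %, ±10 % of the steady-state load, one
paced beat, OLS slope of ΔAPD against ΔCa-peak).

**Cooperative gating.** The activation gate obeys
d(d)/dt = α_d·γ_d·(1−d) − β_d·d with

    γ_d = 1 + gain · w · σ(15(po_Ca − po_x)) · σ(c_s − cs_x),  po_Ca = d·f·f_Ca.

The printed-scale prefactor of 0.01 would bound the activation-rate change
at 1 % for w = 1; since d ≤ 1, no feedback can turn a 1 % rate change into
the ~1.5-fold peak-current amplification this coupling is defined by. The
package therefore treats the prefactor as a calibration constant
(`coup_gain`, default 3.0, chosen once against the 1.5× step-clamp
amplification at w = 1); the printed scale remains available through the
parameter. The activation time constant carries a ×12 scale factor
(`tau_d_scale`) representing the slower collective recruitment of a
cluster compared to a single gate; the amplification mechanism is a race
between γ_d-accelerated activation and fast Ca-dependent inactivation.
With w = 0 the model is the base model exactly (γ_d ≡ 1).

**Known limitation.** With the calibrated gain, w ≳ 2 produces so much
window current that the AP fails to repolarise (the cell leaves the 1:1
regime); monotone APD prolongation is therefore established over
w ∈ {0, 0.3, 1}, while I-V peak growth is monotone through w = 5.

**Numerics.** Forward Euler for V and the Ca pools plus exact
exponential (Rush–Larsen) gate updates, dt = 0.01 ms by default. The
Luo–Rudy m-gate makes classical RK4 unstable for dt ≥ 0.02 ms at resting
potential (β_m·dt > 2.8), which is why the splitting scheme is used. The
scheme is first-order: APD carries a ~0.3 ms discretisation bias at
dt = 0.01 that is uniform across compared conditions; halving dt from
0.0025 changes APD by < 0.1 ms. Gates are clipped to [0, 1] and
concentrations to ≥ 0; blow-up (|V| > 500 mV or non-finite) raises an
error.

## 3. Map theory and beat-series analysis

The coupled-map eigenvalues λ± = ½(−λ_v − λ_c ± √((λ_c − λ_v)² + 4C)) are
implemented in closed form; classification is stable (|λ|max < 1),
alternans (real dominant eigenvalue beyond the unit circle) or
quasiperiodic (complex dominant pair, |λ|² = λ_vλ_c − C > 1). Stability
boundaries over (λ_v, λ_c) grids reproduce the uncoupled square boundary
at C = 0 and shrink with more positive (or less negative) C.

APD is measured at 90 % repolarisation from the maximum-upstroke time
(threshold configurable); upstroke detections within 50 ms are merged
(stimulus artifact and Na⁺ spike belong to one beat) and deflections
smaller than 20 mV are not counted as APs. Alternans amplitude is
ΔAPD_n = (−1)ⁿ(APD_{n+1} − APD_n); the Ca amplitude uses the analogous
difference. (The corresponding printed formula is a sum, which for a
period-2 rhythm measures the mean rather than the alternation; the
difference form is used by default and the literal sum is available via
``printed_sum=True``.) Sustained alternans requires |ΔAPD| above 1 ms with
a constant alternation phase for 10 consecutive beats; Ca alternans
requires > 2 % relative peak alternation. Quasiperiodicity in simulated
beat series is detected spectrally (dominant discrete frequency away from
½ cycle/beat by more than 0.02).

## 4. Synthetic data and what the tests show

All test inputs are generated in code: square/triangle AP waveforms with
closed-form APDs, period-2 beat series, Boltzmann-activation I-V sets
multiplied by the GHK driving force, and open-count traces with known
event structure (`io.make_fixture`). Passing the analysis-layer tests
shows the estimators are exact on clean, noise-free signals; it does not
establish robustness to experimental noise, drift or fractionated
upstrokes, which real recordings contain and these fixtures deliberately
do not.

Desk-scale stochastic runs (≤512 CRUs, ≤100 beats) establish the
*direction and approximate size* of cooperative-gating effects
(amplification, activation shift, alternans onset) under the stated
conditions; they are not pixel-level reproductions of full-cell traces,
whose fluctuation amplitude is ~6× smaller.

## 5. Parameter provenance

Everything the cooperative-gating formulation itself specifies (the
7-state rate expressions, γ factors, GHK current, the five CRU balance
equations, the ionic model's printed gating/Ca equations, the map
eigenvalues, alternans definitions) is implemented as stated. Base-model
constants that the formulation inherits from the rabbit-myocyte modelling
lineage but does not print (compartment volumes, buffer capacities,
diffusion and refill times, K⁺-current formulations and conductances,
SERCA/NCX scales) are adopted as physiologically standard values and
calibrated once against macroscopic targets — resting state near −86 mV,
APD ≈ 200 ms at PCL 300 ms, Ca transient ~0.3–1 µM, stable SR load, the
1.5× amplification, spark size 5–10 RyRs, and the signs of the Ca→V
coupling — all collected with comments in `constants.py`. They are this
package's own parameterisation of that lineage, not verbatim table values.
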