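# coopgate

Stochastic and deterministic models of **cooperative (coupled) gating of
L-type Ca²⁺ channels (LTCCs)** in ventricular myocytes, and of its effect on
cardiac **alternans** — the beat-to-beat period-2 oscillation of action
potential duration (APD) and Ca²⁺-transient amplitude that precedes many
arrhythmias.

LTCCs sit in sarcolemmal clusters of ~10 channels facing ~100 ryanodine
receptors (RyRs) across a dyadic cleft. Experimentally, clustered LTCCs can
gate cooperatively: an open channel and the Ca²⁺ it admits increase its
neighbours' opening rates. `coopgate` implements this as voltage- and
Ca²⁺-dependent multiplicative factors on the Markov-chain activation rates,

    gamma = 1 + w · sigma(15(N_L/3 − po_x)) · sigma(c_p − cp_x),

where `N_L` is the cluster's open count, `c_p` the cleft Ca²⁺ and `w` the
coupling strength (`w = 0` recovers independent gating exactly), and asks
what this does to the whole-cell current, the action potential and the
stability of the paced rhythm.

## What is in the package

| module | contents |
|---|---|
| `coopgate.ltcc` | 7-state LTCC Markov scheme, cooperativity factors, GHK single-channel current, stochastic cluster simulation |
| `coopgate.cru` | Ca²⁺ release unit: 5 local Ca²⁺ pools, 4-state stochastic RyR cluster (spark-calibrated), lattice construction |
| `coopgate.geometry` | 65×27×11 CRU lattice (19,305 CRUs), Gaussian cluster sizes |
| `coopgate.stochastic_cell` | whole-cell stochastic model: voltage clamp, AP clamp, current-clamp pacing (numba kernels) |
| `coopgate.ionic` | deterministic Shiferaw-type AP + Ca-cycling model with the `gamma_d` coupled activation gate |
| `coopgate.alternans` | APD measurement, alternans amplitudes ΔAPD = (−1)ⁿ(APDₙ₊₁ − APDₙ), coupled-map eigenvalues λ± = ½(−λᵥ−λ꜀ ± √((λ꜀−λᵥ)²+4C)), stability classification, Ca→V coupling slope |
| `coopgate.protocols` | I-V/activation curves (Boltzmann fit), (τ_f, u) stability scans, APD-prolongation curves, G_Kr-reduction control |
| `coopgate.io`, `coopgate.cli` | configs, CSV/JSON outputs, run manifests, fixtures, the `coopgate` command line |

## Worked example

Coupled vs uncoupled whole-cell L-type current on a step from −80 to
+20 mV, on a desk-scale 512-CRU lattice with matched seeds:

```python
import numpy as np
from coopgate.cru import build_cell
from coopgate.geometry import CellGeometry
from coopgate.ltcc import LtccParams
from coopgate.stochastic_cell import ClampProtocol, run_voltage_clamp

cell = build_cell(CellGeometry.reduced(16, 8, 4), seed=1)
prot = ClampProtocol(kind="voltage_step", holding=-80.0,
                     test_potentials=(20.0,), hold_duration=20.0,
                     step_duration=150.0)
off = run_voltage_clamp(cell, prot, seed=42,
                        params=LtccParams().uncoupled())[20.0]
on = run_voltage_clamp(cell, prot, seed=42, params=LtccParams())[20.0]
print(f"peak I_CaL uncoupled: {off.ical.min():.2f} A/F")
print(f"peak I_CaL coupled:   {on.ical.min():.2f} A/F")
print(f"ratio: {on.ical.min() / off.ical.min():.2f}")
```

prints

```
peak I_CaL uncoupled: -4.00 A/F
peak I_CaL coupled:   -5.76 A/F
ratio: 1.44
```

— cooperative gating amplifies the peak Ca²⁺ current about 1.5-fold, the
amplification the coupling parameters are calibrated to. The same model
shifts the activation curve leftward, prolongs the AP, and promotes
alternans when paced at a 300 ms cycle length; the deterministic model and
the coupled-map theory (`coopgate.alternans.map_eigenvalues`) show the
underlying mechanism: coupling makes the Ca→V feedback more positive and
shrinks the stable region of the paced rhythm.

The map theory in three lines:

```python
from coopgate.alternans import MapParams, classify_map
print(classify_map(MapParams(lambda_v=0.6, lambda_c=0.6, coupling=0.10)))  # stable
print(classify_map(MapParams(lambda_v=0.6, lambda_c=0.6, coupling=0.20)))  # alternans
```

## Command line

```sh
coopgate stochastic pace --seed 1 --out runs/     # paced lattice cell
coopgate ionic pace --seed 1 --out runs/          # deterministic model
coopgate map -c 0.1 --out map.csv                 # stability boundary grid
coopgate scan apd --out runs/                     # APD vs coupling strength
```

Outputs are CSV traces and JSON summaries plus a manifest with seeds and
checksums; every run is reproducible from its manifest.

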