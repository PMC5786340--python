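"""Whole-cell stochastic simulation: the CRU lattice coupled to a membrane.

Three protocols are provided:

* :func:`run_voltage_clamp` -- step depolarisations from a holding
  potential; the commanded waveform is imposed exactly.
* :func:`run_paced` -- free-running membrane potential with a periodic
  stimulus current; per-beat APD and Ca-peak series are extracted with
  :mod:`coopgate.alternans`.
* :func:`run_ap_clamp` -- the voltage is forced to a recorded AP waveform
  every beat, isolating the Ca-cycling dynamics.

Whole-cell I_CaL is the capacitance-normalised sum of the cluster currents;
all randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from ._kernels import params_array, run_lattice
from .alternans import BeatSeries, apd_per_window, peak_per_beat
from .cru import CellState, build_cell
from .geometry import CellGeometry
from .ltcc import LtccParams

__all__ = ["ClampProtocol", "Trace", "run_voltage_clamp", "run_paced",
           "run_ap_clamp", "default_ap_waveform"]

DT_DEFAULT = 0.01  # ms


@dataclass(frozen=True)
class ClampProtocol:
    """Stimulation protocol description.

    ``kind`` is one of ``voltage_step`` (holding potential, list of test
    potentials), ``ap_waveform`` (periodic commanded waveform) or ``paced``
    (current stimulus every PCL).
    """

    kind: str = "voltage_step"
    holding: float = -80.0           # mV
    test_potentials: tuple = (20.0,)  # mV
    hold_duration: float = 50.0      # ms before the step
    step_duration: float = 200.0     # ms
    pcl: float = 300.0               # ms
    n_beats: int = 10
    stim_amp: float = K.STIM_AMP     # A/F
    stim_dur: float = K.STIM_DUR     # ms

    def __post_init__(self) -> None:
        if self.step_duration <= 0 or self.pcl <= 0:
            raise ValueError("durations must be positive")
        if self.kind == "paced" and self.pcl <= self.stim_dur:
            raise ValueError("PCL must exceed the stimulus duration")


@dataclass
class Trace:
    """Recorded whole-cell time series (stride-subsampled)."""

    t: np.ndarray
    vm: np.ndarray
    ical: np.ndarray     # A/F
    incx: np.ndarray     # A/F
    ci: np.ndarray       # uM, lattice mean
    cs: np.ndarray
    cjsr: np.ndarray
    cp: np.ndarray
    n_open: np.ndarray   # mean open LTCCs per CRU
    meta: dict = field(default_factory=dict)


def _run(cell: CellState, mode: int, v_cmd: np.ndarray, istim: np.ndarray,
         dt: float, stride: int, seed: int, params: LtccParams,
         overrides: dict | None = None, clamp_channels: bool = False) -> Trace:
    P = params_array(params, **(overrides or {}))
    n_steps = v_cmd.size
    n_rec = (n_steps + stride - 1) // stride
    out = [np.zeros(n_rec) for _ in range(8)]
    g = cell.geometry
    n_clamped = run_lattice(
        mode, v_cmd, istim, n_steps, dt, stride,
        g.nx, g.ny, g.nz, cell.chan_state, cell.chan_off,
        cell.ryr, cell.ci, cell.cs, cell.cp, cell.cnsr, cell.cjsr,
        cell.bti, cell.bts, cell.mem, P, seed, clamp_channels,
        out[0], out[1], out[2], out[3], out[4], out[5], out[6], out[7])
    t = np.arange(n_rec) * dt * stride
    return Trace(t=t, vm=out[0], ical=out[1], incx=out[2], ci=out[3],
                 cs=out[4], cjsr=out[5], cp=out[7], n_open=out[6],
                 meta={"seed": seed, "dt": dt, "n_clamped": int(n_clamped),
                       "n_cru": g.n_cru})


def run_voltage_clamp(cell: CellState, protocol: ClampProtocol, seed: int,
                      params: LtccParams | None = None, dt: float = DT_DEFAULT,
                      stride: int = 10, overrides: dict | None = None):
    """Step-depolarisation protocol; returns ``{V_test: Trace}``.

    Each test potential starts from an identical copy of ``cell`` and an
    identical RNG stream, so coupled/uncoupled comparisons with matched
    seeds differ only through the gating model.
    """
    if protocol.kind != "voltage_step":
        raise ValueError("protocol.kind must be 'voltage_step'")
    p = params or LtccParams()
    traces = {}
    n_hold = int(round(protocol.hold_duration / dt))
    n_step = int(round(protocol.step_duration / dt))
    for v_test in protocol.test_potentials:
        v_cmd = np.concatenate([np.full(n_hold, protocol.holding),
                                np.full(n_step, float(v_test))])
        istim = np.zeros_like(v_cmd)
        traces[float(v_test)] = _run(cell.copy(), 0, v_cmd, istim, dt, stride,
                                     seed, p, overrides)
    return traces


def run_paced(cell: CellState, protocol: ClampProtocol, seed: int,
              params: LtccParams | None = None, dt: float = DT_DEFAULT,
              stride: int = 20, overrides: dict | None = None):
    """Pace the free-running cell; returns ``(Trace, BeatSeries)``.

    The stimulus current ``stim_amp`` is injected for ``stim_dur`` ms at
    the start of every cycle.  APD is measured at 90 % repolarisation; the
    Ca-peak series is the per-cycle maximum of the lattice-mean cytosolic
    Ca.
    """
    if protocol.kind != "paced":
        raise ValueError("protocol.kind must be 'paced'")
    p = params or LtccParams()
    n_steps = int(round(protocol.n_beats * protocol.pcl / dt))
    istim = np.zeros(n_steps)
    n_stim = int(round(protocol.stim_dur / dt))
    per_beat = int(round(protocol.pcl / dt))
    for b in range(protocol.n_beats):
        istim[b * per_beat: b * per_beat + n_stim] = protocol.stim_amp
    v_cmd = np.zeros(n_steps)
    trace = _run(cell, 1, v_cmd, istim, dt, stride, seed, p, overrides)
    apd = apd_per_window(trace.t, trace.vm, protocol.pcl)
    peaks = peak_per_beat(trace.t, trace.ci, protocol.pcl)
    n = min(apd.size, peaks.size)
    series = BeatSeries(apd=apd[:n], ca_peak=peaks[:n], pcl=protocol.pcl)
    return trace, series


def run_ap_clamp(cell: CellState, waveform: np.ndarray, n_beats: int,
                 seed: int, params: LtccParams | None = None,
                 dt: float = DT_DEFAULT, stride: int = 20,
                 overrides: dict | None = None):
    """Clamp V to ``waveform`` (one PCL, sampled at ``dt``) for ``n_beats``
    beats; returns ``(Trace, ca_peak_series)``."""
    p = params or LtccParams()
    v_cmd = np.tile(np.asarray(waveform, dtype=float), n_beats)
    istim = np.zeros_like(v_cmd)
    trace = _run(cell, 0, v_cmd, istim, dt, stride, seed, p, overrides)
    pcl = waveform.size * dt
    peaks = peak_per_beat(trace.t, trace.ci, pcl)
    return trace, peaks


def default_ap_waveform(pcl: float = 300.0, apd: float = 230.0,
                        dt: float = DT_DEFAULT, v_rest: float = -80.0,
                        v_peak: float = 35.0, v_plateau: float = 15.0) -> np.ndarray:
    """Stylised ventricular AP waveform (spike, plateau, repolarisation)
    used by the AP-clamp protocol when no recorded AP is supplied."""
    n = int(round(pcl / dt))
    t = np.arange(n) * dt
    v = np.full(n, v_rest)
    up = t < 2.0
    v[up] = v_rest + (v_peak - v_rest) * (t[up] / 2.0)
    # early repolarisation to plateau, then slow decay and final fall
    phase2 = (t >= 2.0) & (t < apd)
    tau_fall = 35.0
    x = (t[phase2] - 2.0) / (apd - 2.0)
    plateau = v_plateau - 8.0 * x
    fall = (v_rest - plateau) * np.exp(-(apd - t[phase2]) / tau_fall)
    v[phase2] = plateau + fall + (v_peak - v_plateau) * np.exp(-(t[phase2] - 2.0) / 3.0)
    return v
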