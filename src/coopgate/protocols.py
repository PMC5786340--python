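"""Reusable experiment drivers shared by the stochastic and ionic models.

* I-V and activation curves from step-depolarisation protocols, with a
  Boltzmann fit of the normalised activation curve.
* Stability scans over the (tau_f, u) plane (APD-restitution steepness vs
  SR release-load steepness) comparing two coupling strengths.
* APD-prolongation curves over coupling strength.
* The G_Kr-reduction control (AP prolongation without the coupling-induced
  change in Ca_i -> V_m coupling).

All drivers record full provenance (parameters, seeds) in their result
objects, and paired coupled/uncoupled stochastic runs share seeds so that
differences are attributable to gating, not sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import constants as K
from .alternans import (BeatSeries, alternans_amplitudes,
                        sustained_alternans_onset, STABLE, ALTERNANS,
                        QUASIPERIODIC)
from .ionic import IonicParams, pace, voltage_clamp
from .ltcc import LtccParams, single_channel_current

__all__ = ["IvCurve", "ScanResult", "iv_activation_curves",
           "stochastic_iv_runner", "ionic_iv_runner", "classify_beat_series",
           "stability_scan", "apd_prolongation_curve", "gk_reduction_control"]


@dataclass
class IvCurve:
    """Peak-current and activation data over test potentials."""

    test_potentials: np.ndarray   # mV
    peak_current: np.ndarray      # A/F (inward negative)
    activation: np.ndarray        # normalised, in [0, 1] (NaN near reversal)
    v_half: float                 # mV, Boltzmann midpoint
    slope: float                  # mV, Boltzmann slope factor
    meta: dict = field(default_factory=dict)


def _boltzmann(v, v_half, k):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


def iv_activation_curves(runner, test_potentials=None,
                         cp_ref: float = 0.5,
                         ltcc_params: LtccParams | None = None,
                         smooth_ms: float = 2.0) -> IvCurve:
    """I-V curve and Boltzmann-fitted activation curve.

    ``runner(v_test) -> (t, ical)`` returns the whole-cell current trace of
    a step from the holding potential to ``v_test``.  Traces are smoothed
    with a ``smooth_ms`` boxcar before peak extraction so that isolated
    single-channel openings (large on a desk-scale lattice) do not
    masquerade as ensemble peaks.  The activation curve is the peak inward
    current divided by the single-channel driving force at that potential
    (GHK current at a reference cleft Ca), normalised to its maximum;
    potentials where the driving force nearly vanishes are excluded from
    the Boltzmann fit.
    """
    vs = np.asarray(test_potentials if test_potentials is not None
                    else np.arange(-60.0, 61.0, 10.0), dtype=float)
    lp = ltcc_params or LtccParams()
    peaks = np.empty(vs.size)
    for i, v in enumerate(vs):
        t, ical = runner(float(v))
        if smooth_ms > 0.0 and t.size > 2:
            dt_rec = t[1] - t[0]
            n = max(1, int(round(smooth_ms / dt_rec)))
            ical = np.convolve(ical, np.ones(n) / n, mode="same")
        peaks[i] = np.min(ical)
    if np.all(peaks == 0.0):
        raise ValueError("all-zero current traces: cannot fit activation")
    drive = np.array([single_channel_current(float(v), cp_ref, lp) for v in vs])
    act = np.full(vs.size, np.nan)
    ok = np.abs(drive) > 0.02 * np.abs(drive).max()
    act[ok] = peaks[ok] / drive[ok]
    act[ok] /= np.nanmax(act[ok])
    m = ok & np.isfinite(act)
    # Ca-dependent inactivation depresses the peaks at strongly positive
    # potentials, so the driving-force-normalised curve is non-monotone;
    # fit the Boltzmann over the rising limb only (up to the maximum).
    i_max = int(np.nanargmax(np.where(m, act, -np.inf)))
    m &= np.arange(vs.size) <= i_max
    p0 = (-10.0, 6.0)
    popt, _ = curve_fit(_boltzmann, vs[m], act[m], p0=p0, maxfev=10000)
    return IvCurve(test_potentials=vs, peak_current=peaks, activation=act,
                   v_half=float(popt[0]), slope=float(popt[1]),
                   meta={"cp_ref": cp_ref})


def stochastic_iv_runner(cell, seed: int, params: LtccParams | None = None,
                         hold: float = -80.0, hold_ms: float = 50.0,
                         step_ms: float = 150.0, dt: float = 0.01,
                         overrides: dict | None = None):
    """Runner over the CRU lattice for :func:`iv_activation_curves`."""
    from .stochastic_cell import ClampProtocol, run_voltage_clamp

    def run(v_test):
        prot = ClampProtocol(kind="voltage_step", holding=hold,
                             test_potentials=(v_test,), hold_duration=hold_ms,
                             step_duration=step_ms)
        tr = run_voltage_clamp(cell, prot, seed, params, dt=dt,
                               overrides=overrides)[v_test]
        m = tr.t >= hold_ms
        return tr.t[m] - hold_ms, tr.ical[m]

    return run


def ionic_iv_runner(params: IonicParams, hold: float = -80.0,
                    hold_ms: float = 500.0, step_ms: float = 200.0,
                    dt: float = 0.01):
    """Runner over the deterministic model for :func:`iv_activation_curves`."""

    def run(v_test):
        t, ical, _ = voltage_clamp(params, v_hold=hold, v_test=v_test,
                                   hold_ms=hold_ms, step_ms=step_ms, dt=dt)
        return t, ical

    return run


def classify_beat_series(series: BeatSeries, apd_thresh: float = 1.0,
                         ca_rel_thresh: float = 0.02, tail: int = 20) -> str:
    """Stability class of a simulated beat series.

    ``alternans`` requires a sustained, sign-consistent period-2 APD
    alternation (|dAPD| above threshold) or a relative Ca-peak alternation
    above ``ca_rel_thresh`` over the last ``tail`` beats; ``quasiperiodic``
    requires a sustained oscillation whose dominant discrete frequency is
    incommensurate with 1/2 cycle per beat (tolerance 0.02).
    """
    apd = series.apd[-tail:]
    ca = series.ca_peak[-tail:]
    if apd.size < 4:
        return STABLE
    d = np.diff(apd)
    sign = (-1.0) ** np.arange(d.size)
    d_alt = sign * d
    period2_apd = np.all(np.abs(d) > apd_thresh) and (
        np.all(d_alt > 0) or np.all(d_alt < 0))
    ca_rel = np.abs(np.diff(ca)) / np.maximum(ca[:-1], 1e-12)
    period2_ca = np.all(ca_rel > ca_rel_thresh) and (
        np.all(sign * np.diff(ca) > 0) or np.all(sign * np.diff(ca) < 0))
    osc = apd - apd.mean()
    amp = np.max(np.abs(osc))
    if amp > apd_thresh and not (period2_apd or period2_ca):
        # spectral check for Hopf-type (quasiperiodic) modulation
        spec = np.abs(np.fft.rfft(osc))
        freqs = np.fft.rfftfreq(osc.size)
        spec[0] = 0.0
        fdom = freqs[np.argmax(spec)]
        if abs(fdom - 0.5) > 0.02 and np.sort(spec)[-1] > 2.0 * np.median(spec[1:]):
            return QUASIPERIODIC
    if period2_apd or period2_ca:
        return ALTERNANS
    return STABLE


@dataclass
class ScanResult:
    """Stability classification over a (tau_f, u) grid."""

    tau_f: np.ndarray
    u: np.ndarray
    labels: np.ndarray        # (len(tau_f), len(u)) of class strings
    amplitudes: np.ndarray    # mean |dAPD| of the final beats (ms)
    converged: np.ndarray     # False where the run failed or lost 1:1 capture
    w: float
    pcl: float
    meta: dict = field(default_factory=dict)

    @property
    def stable_cells(self) -> int:
        return int(np.count_nonzero(self.labels == STABLE))

    def stable_per_row(self) -> np.ndarray:
        return (self.labels == STABLE).sum(axis=1)


def _scan_one(params: IonicParams, pcl: float, n_beats: int, dt: float):
    try:
        series, _, steady = pace(params, pcl, n_beats, dt=dt)
    except FloatingPointError:
        return None, None
    if series.apd.size < max(10, n_beats // 2):
        return None, series  # lost 1:1 capture
    return classify_beat_series(series), series


def stability_scan(params: IonicParams, tau_f_grid, u_grid, w: float,
                   pcl: float = 300.0, n_beats: int = 300,
                   dt: float = 0.01) -> ScanResult:
    """Classify steady-state dynamics at every (tau_f, u) for one coupling
    strength; non-converged cells are flagged, not silently classified."""
    tf = np.asarray(tau_f_grid, dtype=float)
    uu = np.asarray(u_grid, dtype=float)
    labels = np.empty((tf.size, uu.size), dtype=object)
    amps = np.zeros((tf.size, uu.size))
    conv = np.ones((tf.size, uu.size), dtype=bool)
    for i, tfi in enumerate(tf):
        for j, uj in enumerate(uu):
            p = params.with_(tau_f=tfi, u=uj, w=w)
            label, series = _scan_one(p, pcl, n_beats, dt)
            if label is None:
                labels[i, j] = "failed"
                conv[i, j] = False
                continue
            labels[i, j] = label
            d_apd, _ = alternans_amplitudes(series)
            amps[i, j] = float(np.mean(np.abs(d_apd[-10:])))
    return ScanResult(tau_f=tf, u=uu, labels=labels, amplitudes=amps,
                      converged=conv, w=w, pcl=pcl,
                      meta={"n_beats": n_beats, "dt": dt})


def apd_prolongation_curve(params: IonicParams, w_list, pcl: float = 400.0,
                           n_beats: int = 300, dt: float = 0.01) -> np.ndarray:
    """Steady-state APD for each coupling strength.

    Raises when alternans develops (the protocol requires a 1:1 response).
    """
    apds = []
    for w in w_list:
        series, _, steady = pace(params.with_(w=w), pcl, n_beats, dt=dt)
        d_apd, _ = alternans_amplitudes(series)
        if sustained_alternans_onset(d_apd) is not None:
            raise RuntimeError(f"alternans at w = {w}: not a 1:1 protocol")
        apds.append(series.apd[-2:].mean())
    return np.asarray(apds)


def gk_reduction_control(params: IonicParams, tau_f_grid, u_grid,
                         gkr_scale: float = 0.5, w: float = 0.0,
                         pcl: float = 300.0, n_beats: int = 300,
                         dt: float = 0.01) -> ScanResult:
    """Stability scan with I_Kr reduced by ``1 - gkr_scale``.

    Control experiment: simple AP prolongation (less repolarising current)
    without any change in the coupling machinery.
    """
    p = params.with_(g_kr=params.g_kr * gkr_scale)
    res = stability_scan(p, tau_f_grid, u_grid, w, pcl, n_beats, dt)
    res.meta["gkr_scale"] = gkr_scale
    return res
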