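"""Beat-series analysis and the two-variable coupled-map stability theory.

Alternans is a period-2 beat-to-beat oscillation of action-potential
duration (APD) and/or Ca-transient amplitude at a constant pacing rate.  Its
onset in the coupled voltage/Ca system is governed by the eigenvalues of a
two-dimensional return map::

    lambda_pm = (-(lambda_v + lambda_c) +- sqrt((lambda_c - lambda_v)^2 + 4C)) / 2

where ``lambda_v`` is the voltage-map (APD-restitution) eigenvalue,
``lambda_c`` the Ca-map (release-load) eigenvalue and ``C`` the signed
Ca_i -> V_m coupling.  The fixed point loses stability when the dominant
eigenvalue leaves the unit circle: through -1 on the real axis (period-2
alternans) or as a complex pair (quasiperiodic, Hopf-type modulation).
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeatSeries",
    "MapParams",
    "measure_apd",
    "peak_per_beat",
    "alternans_amplitudes",
    "sustained_alternans_onset",
    "map_eigenvalues",
    "classify_map",
    "theoretical_boundary",
    "coupling_slope",
    "restitution_eigenvalue",
]

STABLE, ALTERNANS, QUASIPERIODIC = "stable", "alternans", "quasiperiodic"


@dataclass
class BeatSeries:
    """Per-beat APD (ms) and peak cytosolic Ca (uM) at one pacing rate."""

    apd: np.ndarray
    ca_peak: np.ndarray
    pcl: float

    def __post_init__(self) -> None:
        self.apd = np.asarray(self.apd, dtype=float)
        self.ca_peak = np.asarray(self.ca_peak, dtype=float)
        if self.apd.shape != self.ca_peak.shape:
            raise ValueError("apd and ca_peak must have equal length")


@dataclass(frozen=True)
class MapParams:
    """Eigenvalues of the uncoupled maps and the Ca_i->V_m coupling."""

    lambda_v: float
    lambda_c: float
    coupling: float


def measure_apd(t: np.ndarray, vm: np.ndarray,
                repolarization_fraction: float = 0.9) -> np.ndarray:
    """APD per beat from a membrane-potential trace.

    A beat starts at a maximum-upstroke-velocity point (dV/dt above 5 mV/ms,
    local maximum of dV/dt) and ends when V crosses
    ``V_rest + (1 - fraction)(V_peak - V_rest)`` downward -- APD90 by
    default.  Returns an empty array when no upstroke is detected.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if vm.size < 3:
        return np.array([])
    dvdt = np.gradient(vm, t)
    above = dvdt > 5.0
    # upstroke = first sample of each run of fast-depolarising samples
    idx = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above[0]:
        idx = np.concatenate(([0], idx))
    if idx.size == 0:
        return np.array([])
    # merge detections within a 50 ms refractory window (stimulus artifact
    # and Na upstroke belong to the same beat)
    merged = [idx[0]]
    for i in idx[1:]:
        if t[i] - t[merged[-1]] > 50.0:
            merged.append(i)
    idx = np.asarray(merged)
    v_rest = float(np.min(vm))
    apds = []
    bounds = list(idx) + [vm.size]
    for k in range(len(idx)):
        a, b = idx[k], bounds[k + 1]
        # include the next beat's first sample so a crossing that lands
        # exactly on the boundary is attributed to this beat
        seg = vm[a:min(b + 1, vm.size)]
        v_peak = float(seg.max())
        if v_peak - v_rest < 20.0:
            continue  # subthreshold blip, not an AP
        thr = v_rest + (1.0 - repolarization_fraction) * (v_peak - v_rest)
        below = np.nonzero(seg <= thr)[0]
        # skip leading samples still below threshold before the upstroke tops
        below = below[below > int(np.argmax(seg >= thr))] if np.any(seg >= thr) else below
        if below.size == 0:
            continue  # did not repolarise within this beat window
        j = a + below[0]
        # linear interpolation of the crossing time
        if j > a and vm[j - 1] > thr:
            frac = (vm[j - 1] - thr) / (vm[j - 1] - vm[j])
            t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
        else:
            t_cross = t[j]
        apds.append(t_cross - t[a])
    return np.asarray(apds)


def apd_per_window(t: np.ndarray, vm: np.ndarray, pcl: float,
                   repolarization_fraction: float = 0.9) -> np.ndarray:
    """APD per pacing window for stimulus-aligned protocols.

    Each window [n*PCL, (n+1)*PCL) yields one APD: time from the window
    start to the 90 %-repolarisation crossing.  A beat that has not
    repolarised when the next stimulus arrives is censored at the window
    length (the natural reading for 2:2 rhythms, where long beats span the
    whole cycle); windows without an AP (peak < rest + 20 mV) give NaN.
    Keeps one entry per beat, so alternans phase is never lost.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    n_beats = int(np.floor((t[-1]) / pcl - 1.0e-9)) + 1
    v_rest = float(np.min(vm))
    out = np.full(n_beats, np.nan)
    for n in range(n_beats):
        m = (t >= n * pcl) & (t < (n + 1) * pcl)
        seg = vm[m]
        if seg.size < 3:
            continue
        v_peak = float(seg.max())
        if v_peak - v_rest < 20.0:
            continue
        thr = v_rest + (1.0 - repolarization_fraction) * (v_peak - v_rest)
        i_peak = int(np.argmax(seg))
        below = np.nonzero(seg[i_peak:] <= thr)[0]
        if below.size == 0:
            out[n] = pcl  # censored: no repolarisation within the cycle
        else:
            j = i_peak + below[0]
            tm = t[m]
            out[n] = tm[j] - tm[0]
    return out


def peak_per_beat(t: np.ndarray, ca: np.ndarray, pcl: float,
                  t0: float = 0.0) -> np.ndarray:
    """Peak of a Ca trace within each pacing window [t0 + n*PCL, t0 + (n+1)*PCL)."""
    t = np.asarray(t, dtype=float)
    ca = np.asarray(ca, dtype=float)
    n_beats = int(np.floor((t[-1] - t0) / pcl - 1.0e-9)) + 1
    peaks = np.empty(n_beats)
    for n in range(n_beats):
        m = (t >= t0 + n * pcl) & (t < t0 + (n + 1) * pcl)
        peaks[n] = ca[m].max() if np.any(m) else np.nan
    return peaks


def alternans_amplitudes(series: BeatSeries, printed_sum: bool = False):
    """Alternans amplitudes dAPD_n = (-1)^n (APD_{n+1} - APD_n) and the
    Ca analogue.

    ``printed_sum=True`` switches the Ca amplitude to the literal
    ``(-1)^n (Ca_{n+1} + Ca_n)`` form; the default uses the difference,
    matching the APD definition (see docs/methods.md).
    """
    apd, ca = series.apd, series.ca_peak
    if apd.size < 2:
        raise ValueError("need at least 2 beats")
    n = np.arange(apd.size - 1)
    sign = (-1.0) ** n
    d_apd = sign * (apd[1:] - apd[:-1])
    d_ca = sign * (ca[1:] + ca[:-1]) if printed_sum else sign * (ca[1:] - ca[:-1])
    return d_apd, d_ca


def sustained_alternans_onset(d_apd: np.ndarray, threshold: float = 1.0,
                              run: int = 10) -> int | None:
    """First beat index n at which |dAPD| stays above ``threshold`` (ms) with
    a constant sign of alternation for ``run`` consecutive beats.  None when
    alternans is never sustained."""
    d = np.asarray(d_apd, dtype=float)
    for n in range(d.size - run + 1):
        w = d[n:n + run]
        if np.any(~np.isfinite(w)):
            continue
        if np.all(np.abs(w) > threshold) and (np.all(w > 0) or np.all(w < 0)):
            return n
    return None


def map_eigenvalues(p: MapParams) -> tuple[complex, complex]:
    """Closed-form eigenvalues of the coupled two-variable map."""
    disc = (p.lambda_c - p.lambda_v) ** 2 + 4.0 * p.coupling
    root = cmath.sqrt(disc)
    lam_p = 0.5 * (-p.lambda_v - p.lambda_c + root)
    lam_m = 0.5 * (-p.lambda_v - p.lambda_c - root)
    return lam_p, lam_m


def classify_map(p: MapParams) -> str:
    """Stability class of the coupled map at these parameters."""
    lam_p, lam_m = map_eigenvalues(p)
    dominant = lam_p if abs(lam_p) >= abs(lam_m) else lam_m
    if abs(dominant) < 1.0:
        return STABLE
    if abs(dominant.imag) > 0.0:
        return QUASIPERIODIC
    return ALTERNANS


@dataclass
class StabilityMap:
    """Classification over a (lambda_v, lambda_c) grid at fixed coupling."""

    lambda_v: np.ndarray
    lambda_c: np.ndarray
    labels: np.ndarray      # 2-D array of class strings
    coupling: float

    @property
    def stable_cells(self) -> int:
        return int(np.count_nonzero(self.labels == STABLE))


def theoretical_boundary(coupling: float, lambda_v_grid: np.ndarray,
                         lambda_c_grid: np.ndarray) -> StabilityMap:
    """Classify every grid point; the |lambda| = 1 contour is the boundary."""
    lv = np.asarray(lambda_v_grid, dtype=float)
    lc = np.asarray(lambda_c_grid, dtype=float)
    labels = np.empty((lv.size, lc.size), dtype=object)
    for i, a in enumerate(lv):
        for j, b in enumerate(lc):
            labels[i, j] = classify_map(MapParams(a, b, coupling))
    return StabilityMap(lv, lc, labels, coupling)


def coupling_slope(points) -> float:
    """Ordinary least-squares slope of dAPD against dCa_peak.

    ``points`` is a sequence of (dCa_peak, dAPD) perturbation results; a
    positive slope means positive Ca_i -> V_m coupling (NCX-dominated), a
    negative slope Ca-inactivation-dominated behaviour.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 perturbation points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate perturbations: zero variance in dCa")
    return float(np.polyfit(x, y, 1)[0])


def restitution_eigenvalue(di: np.ndarray, apd: np.ndarray) -> float:
    """Optional utility: lambda_v estimated as the slope of the APD
    restitution curve APD(DI) at its steep end (largest-slope secant)."""
    di = np.asarray(di, dtype=float)
    apd = np.asarray(apd, dtype=float)
    order = np.argsort(di)
    di, apd = di[order], apd[order]
    slopes = np.diff(apd) / np.diff(di)
    return float(np.max(slopes))
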